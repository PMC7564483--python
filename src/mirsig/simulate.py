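"""Synthetic plasma-miRNA cohort generator.

Emulates the two-platform study design the pipeline analyzes: a small NGS
training set (a few control and case small-RNA libraries over ~2,000
miRNAs) and a larger ddPCR validation cohort quantified in copies/µL. A
planted subset of miRNAs carries true case-vs-control fold changes (up or
down), a designated subset is additionally shifted in KRAS-mutant cases,
and a low-abundance stratum sits below the ddPCR reliability floor so the
screen's abundance filter has something to do.

Generative model
----------------
* Per-miRNA baseline plasma abundance b_m (copies/µL): log-uniform over
  ``baseline_log_mean_range``; the low-abundance stratum is drawn below
  0.2 copies/µL instead.
* ddPCR value for sample s, miRNA m: log-normal with mean
  b_m x effect(s, m), coefficient of variation ``noise_cv``. Effects are
  multiplicative: planted UP miRNAs are multiplied by ``effect_fc`` in
  affected cases, DOWN divided; KRAS-target miRNAs are further multiplied
  by ``kras_effect_fc`` in mutant cases. Log-normality keeps values
  positive and matches the orders-of-magnitude spread of plasma miRNAs.
* NGS count for library s, miRNA m: negative binomial with mean
  b_m x counts_per_copy x effect(s, m) x size_factor_s and dispersion
  ``dispersion`` (variance mu + dispersion x mu^2); size factors are
  log-uniform in [0.5, 2] to exercise depth normalization. The NGS
  training libraries are the first few samples of each ddPCR group, as in
  a nested training/validation design.

All randomness flows from one ``numpy`` generator seeded by ``seed``, so a
config reproduces its cohort bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .screen import CASE, CONTROL, CountMatrix

WT = "WT"
MUT = "MUT"
NA = "NA"

UP = "UP"
DOWN = "DOWN"
NULL = "NULL"


@dataclass
class SimConfig:
    """Study-design and noise parameters of the synthetic cohort.

    Defaults reproduce the analyzed design: a 3-control / 5-case NGS
    training set over 2,000 miRNAs nested in a 6-control / 35-case ddPCR
    cohort, a 9-miRNA planted signature (5 up, 4 down), and a KRAS-mutant
    fraction of 16/27 among cases.
    """

    n_controls_ngs: int = 3
    n_cases_ngs: int = 5
    n_controls_ddpcr: int = 6
    n_cases_ddpcr: int = 35
    n_mirnas: int = 2000
    n_planted_up: int = 5
    n_planted_down: int = 4
    effect_fc: float = 4.0
    #: natural-log copies/µL interval for baseline plasma abundances
    baseline_log_mean_range: tuple[float, float] = (np.log(0.5), np.log(500.0))
    #: expected NGS reads per plasma copy/µL at unit size factor
    counts_per_copy: float = 20.0
    #: negative-binomial overdispersion of counts (0 -> Poisson)
    dispersion: float = 0.2
    #: coefficient of variation of the multiplicative ddPCR noise
    noise_cv: float = 0.2
    #: fraction of miRNAs in the low-abundance stratum (< 0.2 copies/µL)
    low_abundance_fraction: float = 0.1
    kras_mut_fraction: float = 16 / 27
    kras_effect_fc: float = 4.0
    n_kras_mirnas: int = 3
    #: null miRNAs added to the ddPCR panel besides the planted ones
    ddpcr_panel_extra: int = 30
    #: fraction of cases actually carrying the planted effects
    affected_fraction: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_controls_ngs": self.n_controls_ngs,
            "n_cases_ngs": self.n_cases_ngs,
            "n_controls_ddpcr": self.n_controls_ddpcr,
            "n_cases_ddpcr": self.n_cases_ddpcr,
            "n_mirnas": self.n_mirnas,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1")
        if self.n_planted_up < 0 or self.n_planted_down < 0:
            raise ConfigurationError("n_planted_up/n_planted_down must be >= 0")
        if self.n_planted_up + self.n_planted_down > self.n_mirnas:
            raise ConfigurationError(
                "n_planted_up + n_planted_down must not exceed n_mirnas"
            )
        if self.effect_fc <= 0:
            raise ConfigurationError("effect_fc must be positive")
        if self.kras_effect_fc <= 0:
            raise ConfigurationError("kras_effect_fc must be positive")
        lo, hi = self.baseline_log_mean_range
        if not lo <= hi:
            raise ConfigurationError("baseline_log_mean_range must be ordered")
        if self.counts_per_copy <= 0:
            raise ConfigurationError("counts_per_copy must be positive")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if not 0 <= self.low_abundance_fraction < 1:
            raise ConfigurationError("low_abundance_fraction must lie in [0, 1)")
        if not 0 < self.kras_mut_fraction < 1:
            raise ConfigurationError("kras_mut_fraction must lie in (0, 1)")
        if not 0 <= self.affected_fraction <= 1:
            raise ConfigurationError("affected_fraction must lie in [0, 1]")
        if self.n_kras_mirnas < 0:
            raise ConfigurationError("n_kras_mirnas must be >= 0")
        if self.n_controls_ngs > self.n_controls_ddpcr:
            raise ConfigurationError(
                "n_controls_ngs must not exceed n_controls_ddpcr (nested design)"
            )
        if self.n_cases_ngs > self.n_cases_ddpcr:
            raise ConfigurationError(
                "n_cases_ngs must not exceed n_cases_ddpcr (nested design)"
            )


@dataclass
class Cohort:
    """A simulated two-platform cohort plus its ground truth.

    meta
        Indexed by sample id: group (CONTROL/CASE), kras_status (WT/MUT/NA
        — controls are NA), has_effect (whether the sample carries the
        planted fold changes).
    truth
        Indexed by miRNA id: direction (UP/DOWN/NULL), true_fc,
        kras_target, low_abundance, baseline copies/µL.
    """

    counts: CountMatrix
    ddpcr: pd.DataFrame  # long form: sample_id, mirna_id, copies_per_ul
    meta: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig = field(repr=False, default_factory=SimConfig)

    @property
    def panel(self) -> list[str]:
        return sorted(self.ddpcr["mirna_id"].unique())

    def ddpcr_wide(self) -> pd.DataFrame:
        """Samples x miRNAs matrix of copies/µL."""
        return self.ddpcr.pivot(
            index="sample_id", columns="mirna_id", values="copies_per_ul"
        )


def _lognormal(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    """Draws with the requested arithmetic mean and coefficient of variation."""
    if cv == 0:
        return np.array(mean, dtype=float, copy=True)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2))


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_cohort(config: SimConfig | None = None) -> Cohort:
    """Draw a full synthetic cohort from the generative model above."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_mirnas = config.n_mirnas
    width = max(4, len(str(n_mirnas)))
    mirna_ids = np.array([f"miR-{i:0{width}d}" for i in range(1, n_mirnas + 1)])

    # planted directions; a unit fold change is no effect at all
    order = rng.permutation(n_mirnas)
    up_idx = order[: config.n_planted_up]
    down_idx = order[config.n_planted_up : config.n_planted_up + config.n_planted_down]
    direction = np.full(n_mirnas, NULL, dtype=object)
    if config.effect_fc != 1.0:
        direction[up_idx] = UP
        direction[down_idx] = DOWN

    # KRAS-responsive subset: drawn among planted miRNAs (up first), falling
    # back to nulls if the signature is smaller than requested
    planted_idx = np.concatenate([up_idx, down_idx])
    if config.n_kras_mirnas <= len(planted_idx):
        kras_idx = planted_idx[: config.n_kras_mirnas]
    else:
        null_idx = order[config.n_planted_up + config.n_planted_down :]
        extra = null_idx[: config.n_kras_mirnas - len(planted_idx)]
        kras_idx = np.concatenate([planted_idx, extra])
    is_kras_target = np.zeros(n_mirnas, dtype=bool)
    is_kras_target[kras_idx] = True

    # baselines, with a low-abundance stratum below the ddPCR floor
    lo, hi = config.baseline_log_mean_range
    baseline = np.exp(rng.uniform(lo, hi, n_mirnas))
    n_low = int(round(config.low_abundance_fraction * n_mirnas))
    low_idx = rng.choice(n_mirnas, size=n_low, replace=False) if n_low else np.array([], int)
    is_low = np.zeros(n_mirnas, dtype=bool)
    is_low[low_idx] = True
    if n_low:
        baseline[low_idx] = np.exp(rng.uniform(np.log(0.005), np.log(0.1), n_low))

    # samples
    control_ids = [f"TfD{i}" for i in range(1, config.n_controls_ddpcr + 1)]
    case_ids = [f"CRC{i}" for i in range(1, config.n_cases_ddpcr + 1)]
    sample_ids = control_ids + case_ids
    group = np.array([CONTROL] * len(control_ids) + [CASE] * len(case_ids))
    is_case = group == CASE

    kras = np.where(
        is_case,
        np.where(rng.random(len(sample_ids)) < config.kras_mut_fraction, MUT, WT),
        NA,
    )
    kras[~is_case] = NA
    has_effect = is_case & (rng.random(len(sample_ids)) < config.affected_fraction)

    meta = pd.DataFrame(
        {"group": group, "kras_status": kras, "has_effect": has_effect},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # per-(sample, miRNA) multiplicative effect
    effect = np.ones((len(sample_ids), n_mirnas))
    eff_rows = has_effect
    effect[np.ix_(eff_rows, direction == UP)] *= config.effect_fc
    effect[np.ix_(eff_rows, direction == DOWN)] /= config.effect_fc
    mut_rows = (kras == MUT) & is_case
    effect[np.ix_(mut_rows, is_kras_target)] *= config.kras_effect_fc

    # ddPCR panel: planted + KRAS targets + a seeded draw of null miRNAs
    panel_idx = set(planted_idx.tolist()) | set(kras_idx.tolist())
    null_pool = np.array([i for i in range(n_mirnas) if i not in panel_idx])
    n_extra = min(config.ddpcr_panel_extra, len(null_pool))
    if n_extra:
        panel_idx |= set(rng.choice(null_pool, size=n_extra, replace=False).tolist())
    panel_idx = np.array(sorted(panel_idx))

    ddpcr_mean = baseline[None, panel_idx] * effect[:, panel_idx]
    ddpcr_values = _lognormal(rng, ddpcr_mean, config.noise_cv)
    ddpcr = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, len(panel_idx)),
            "mirna_id": np.tile(mirna_ids[panel_idx], len(sample_ids)),
            "copies_per_ul": ddpcr_values.ravel(),
        }
    )

    # NGS training subset: first libraries of each group (nested design)
    ngs_samples = control_ids[: config.n_controls_ngs] + case_ids[: config.n_cases_ngs]
    ngs_pos = [sample_ids.index(s) for s in ngs_samples]
    sf = np.exp(rng.uniform(np.log(0.5), np.log(2.0), len(ngs_samples)))
    count_mean = (
        baseline[None, :]
        * effect[ngs_pos, :]
        * config.counts_per_copy
        * sf[:, None]
    )
    counts_arr = _nb_counts(rng, count_mean, config.dispersion)
    counts = CountMatrix(
        counts=pd.DataFrame(
            counts_arr.T, index=pd.Index(mirna_ids, name="mirna_id"), columns=ngs_samples
        ),
        group=meta.loc[ngs_samples, "group"],
    )

    true_fc = np.where(direction == NULL, 1.0, config.effect_fc)
    truth = pd.DataFrame(
        {
            "direction": direction,
            "true_fc": true_fc,
            "kras_target": is_kras_target,
            "low_abundance": is_low,
            "baseline_copies_per_ul": baseline,
        },
        index=pd.Index(mirna_ids, name="mirna_id"),
    )
    return Cohort(
        counts=counts,
        ddpcr=ddpcr,
        meta=meta,
        truth=truth,
        config=dataclasses.replace(config),
    )
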