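"""Synthetic cohort, QC-run, histology and sequence generators.

The survey's raw data is not deposited anywhere, so every downstream stage
is exercised against synthetic data with the statistical structure the
analyses assume. All distributional forms here are stand-ins chosen by this
package (the survey publications state none): lengths are normal within a
stratum, weight follows a lognormal-noise allometry W = a L^b, mercury is
lognormal (positive, right-skewed), and parasite counts follow a hurdle
model — a Bernoulli infection event at the stratum prevalence, with counts
of infected fish drawn from a zero-truncated negative binomial whose mean
equals the stratum mean intensity (dispersion k = 1 by default, the strong
overdispersion typical of macroparasite burdens). The hurdle factorization
gives independent control of prevalence and intensity, the two quantities
surveys report, and implies mean abundance = prevalence x intensity.

Determinism: one master seed; each stratum draws from its own substream
keyed by (species, season), so adding or reordering strata does not perturb
the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .defaults import DEFAULT_LESION_OCCURRENCE, DEFAULT_PROFILES
from .errors import ConfigurationError, ValidationError
from .model import (
    LESION_CATEGORIES,
    AlignedSequences,
    FishSpecimen,
    HistoProfile,
    SpeciesSeasonProfile,
    TreeNode,
)


@dataclass
class RegressionModel:
    """Planted linear model for abundance: A = b0 + b_hg*Hg + b_cf*CF + noise.

    ``noise_sd`` defaults to 8.0, matching a survey-scale abundance sd of
    ~8.5 parasites/fish of which the linear signal explains only a few
    percent (see docs/methods.md for the derivation).
    """

    beta0: float = 6.728
    beta_hg: float = 6.109
    beta_cf: float = -5.385
    noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError("regression noise_sd must be positive")


@dataclass
class GeneratorConfig:
    profiles: list[SpeciesSeasonProfile] = field(
        default_factory=lambda: list(DEFAULT_PROFILES)
    )
    allometry_b: float = 3.0        # CF is length-stable at exactly 3
    sigma_log_weight: float = 0.08  # lognormal noise of weight about a*L^b
    sigma_log_liver: float = 0.30   # lognormal noise of liver weight
    regression: RegressionModel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_log_weight <= 0 or self.sigma_log_liver <= 0:
            raise ConfigurationError("lognormal noise sds must be positive")
        if not self.profiles:
            raise ConfigurationError("no stratum profiles configured")


def stratum_rng(seed: int, species: str, season: str) -> np.random.Generator:
    """Independent substream per stratum, stable under stratum reordering."""
    key = zlib.crc32(f"{species}|{season}".encode())
    return np.random.default_rng([int(seed), key])


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _ztnb_underlying_mean(mu: float, k: float) -> float:
    """Mean m of the untruncated NB whose zero-truncation has mean mu."""
    if mu <= 1.0 + 1e-9:
        return 0.0

    def f(m):
        p0 = (k / (k + m)) ** k
        return m / (1.0 - p0) - mu

    return brentq(f, 1e-9, 10.0 * mu + 10.0)


def sample_ztnb(rng: np.random.Generator, size: int, mu: float, k: float) -> np.ndarray:
    """Zero-truncated negative binomial with mean ``mu`` and dispersion ``k``."""
    if mu < 1.0:
        raise ConfigurationError("zero-truncated mean intensity must be >= 1")
    m = _ztnb_underlying_mean(mu, k)
    if m == 0.0:
        return np.ones(size, dtype=int)
    p = k / (k + m)
    out = rng.negative_binomial(k, p, size=size)
    while np.any(out == 0):  # rejection step realizes the truncation
        zero = out == 0
        out[zero] = rng.negative_binomial(k, p, size=int(zero.sum()))
    return out.astype(int)


#: Cap on the within-stratum length coefficient of variation. A couple of
#: printed stratum SEs imply length CVs above 1 (implausible for a single
#: species; almost certainly typos); the cap keeps those strata biologically
#: sane and makes the positive-truncation bias negligible everywhere.
MAX_LENGTH_CV = 0.35


def _length_sd(prof: SpeciesSeasonProfile) -> float:
    return min(prof.se_length_cm * np.sqrt(prof.n),
               MAX_LENGTH_CV * prof.mean_length_cm)


def _positive_normal(rng, mean, sd, size):
    x = rng.normal(mean, sd, size=size)
    while np.any(x <= 0):
        bad = x <= 0
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return x


def generate_cohort(config: GeneratorConfig | None = None) -> list[FishSpecimen]:
    """Draw one full cohort: sum(n) specimens across all configured strata.

    Lengths match stratum means exactly in expectation; the allometric
    coefficient is solved per stratum so expected weight matches the target
    weight mean (per-fish CF then centers on 100*W_bar/E[L^3], which differs
    from a reported mean-of-ratios by a Jensen gap). When a regression model
    is configured, parasite counts are overridden by the planted linear
    abundance model, rounded to nonnegative integers.
    """
    config = config or GeneratorConfig()
    b = config.allometry_b
    sw, sl = config.sigma_log_weight, config.sigma_log_liver
    specimens: list[FishSpecimen] = []
    for prof in config.profiles:
        rng = stratum_rng(config.seed, prof.species, prof.season.value)
        n = prof.n
        sd_len = _length_sd(prof)
        length = _positive_normal(rng, prof.mean_length_cm, sd_len, n)
        # second-order moment of L^b about the mean; exact for b = 3
        mu, var = prof.mean_length_cm, sd_len**2
        e_lb = mu**b * (1.0 + b * (b - 1.0) / 2.0 * var / mu**2)
        a = prof.mean_weight_g / e_lb
        weight = a * length**b * np.exp(rng.normal(0.0, sw, n) - sw**2 / 2.0)
        liver = (prof.mean_hsi / 100.0) * weight * np.exp(
            rng.normal(0.0, sl, n) - sl**2 / 2.0
        )
        liver = np.minimum(liver, weight)
        if prof.mean_thg_ugg > 0:
            m_ln, s_ln = _lognormal_params(
                prof.mean_thg_ugg, prof.se_thg_ugg * np.sqrt(n)
            )
            thg = rng.lognormal(m_ln, s_ln, n)
        else:
            thg = np.zeros(n)
        counts = np.zeros(n, dtype=int)
        infected = rng.random(n) < prof.prevalence
        n_inf = int(infected.sum())
        if n_inf and prof.mean_intensity >= 1.0:
            counts[infected] = sample_ztnb(
                rng, n_inf, prof.mean_intensity, prof.dispersion_k
            )
        if config.regression is not None:
            cf = 100.0 * weight / length**3
            reg = config.regression
            raw = (reg.beta0 + reg.beta_hg * thg + reg.beta_cf * cf
                   + rng.normal(0.0, reg.noise_sd, n))
            counts = np.maximum(np.rint(raw), 0).astype(int)
        tag = "r" if prof.season.value == "rainy" else "d"
        code = "".join(w[0] for w in prof.species.split()[:2])
        for i in range(n):
            specimens.append(FishSpecimen(
                id=f"{code}-{tag}{i + 1:03d}",
                species=prof.species,
                season=prof.season,
                length_cm=float(length[i]),
                weight_g=float(weight[i]),
                liver_weight_g=float(liver[i]),
                parasite_count=int(counts[i]),
                thg_ugg=float(thg[i]),
                trophic_level=prof.trophic_level,
            ))
    return specimens


def regression_dataset(
    config: GeneratorConfig, tl_noise: bool = True
) -> pd.DataFrame:
    """Raw-valued planted-regression dataset for coefficient recovery.

    Returns columns hg, cf, tl, abundance with abundance left real-valued
    (no rounding, which would bias coefficient estimates). ``tl_noise``
    replaces the structured species trophic level with an independent
    standard-normal-scaled noise candidate carrying no signal.
    """
    reg = config.regression or RegressionModel()
    rows = []
    rng_tl = np.random.default_rng([int(config.seed), zlib.crc32(b"tl-noise")])
    for prof in config.profiles:
        rng = stratum_rng(config.seed, prof.species, prof.season.value)
        n = prof.n
        sd_len = _length_sd(prof)
        length = _positive_normal(rng, prof.mean_length_cm, sd_len, n)
        mu, var = prof.mean_length_cm, sd_len**2
        b = config.allometry_b
        e_lb = mu**b * (1.0 + b * (b - 1.0) / 2.0 * var / mu**2)
        a = prof.mean_weight_g / e_lb
        sw = config.sigma_log_weight
        weight = a * length**b * np.exp(rng.normal(0.0, sw, n) - sw**2 / 2.0)
        cf = 100.0 * weight / length**3
        if prof.mean_thg_ugg > 0:
            m_ln, s_ln = _lognormal_params(
                prof.mean_thg_ugg, prof.se_thg_ugg * np.sqrt(n)
            )
            hg = rng.lognormal(m_ln, s_ln, n)
        else:
            hg = np.zeros(n)
        eps = rng.normal(0.0, reg.noise_sd, n)
        abundance = reg.beta0 + reg.beta_hg * hg + reg.beta_cf * cf + eps
        tl = np.full(n, prof.trophic_level)
        rows.append(pd.DataFrame({
            "hg": hg, "cf": cf, "tl": tl, "abundance": abundance,
        }))
    df = pd.concat(rows, ignore_index=True)
    if tl_noise:
        df["tl"] = rng_tl.normal(4.0, 0.5, size=len(df))
    return df


def generate_qc_run(
    n_blanks: int,
    n_crm: int,
    crm_reference: float,
    noise_sd: float,
    seed: int,
    n_samples: int = 10,
    sample_mean: float = 0.3,
    n_calibration: int = 5,
) -> pd.DataFrame:
    """Synthetic instrument-QC table: blanks, CRM block, duplicate samples,
    and a calibration series, in the ``io.read_qc_table`` layout.

    Blank readings are |Normal(0, noise_sd)|, CRM readings
    Normal(reference, noise_sd); every sample appears in duplicate. A zero
    noise sd yields an exactly-100% recovery run; negative is rejected.
    """
    if n_blanks < 2 or n_crm < 2:
        raise ConfigurationError("need at least 2 blanks and 2 CRM readings")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be nonnegative")
    rng = np.random.default_rng([int(seed), zlib.crc32(b"qc-run")])
    rows = []
    for v in np.abs(rng.normal(0.0, noise_sd, n_blanks)):
        rows.append(("blank", None, float(v), None))
    for v in rng.normal(crm_reference, noise_sd, n_crm):
        rows.append(("crm", None, float(v), crm_reference))
    for i in range(n_samples):
        true = max(rng.normal(sample_mean, sample_mean / 3.0), 0.01)
        for v in rng.normal(true, noise_sd, 2):  # duplicate analysis
            rows.append(("sample", f"S{i + 1:02d}", float(v), None))
    levels = np.linspace(0.1, 1.0, n_calibration)
    for lev in levels:
        rows.append(("calibration", None,
                     float(lev + rng.normal(0.0, noise_sd)), float(lev)))
    return pd.DataFrame(rows, columns=["kind", "sample_id", "value", "reference"])


_BASES = np.array(list("ACGT"))


def simulate_alignment(tree: TreeNode, length: int, seed: int) -> AlignedSequences:
    """Evolve sequences down a tree under the Jukes-Cantor model.

    The root sequence is uniform over {A, C, G, T}; along a branch of length
    d (expected substitutions/site) each site differs from its parent with
    probability (3/4)(1 - exp(-4d/3)), the changed sites landing uniformly
    on the three other bases. Leaves are returned in tree order.
    """
    if length < 1:
        raise ValidationError("alignment length must be >= 1")
    for leaf in tree.leaves():
        if leaf.name is None:
            raise ValidationError("all leaves must be named")
    rng = np.random.default_rng([int(seed), zlib.crc32(b"jc-sim")])
    root_seq = rng.integers(0, 4, size=length)
    records: list[tuple[str, str]] = []

    def evolve(parent: np.ndarray, node: TreeNode) -> None:
        d = node.length or 0.0
        if d < 0:
            raise ValidationError(f"negative branch length {d}")
        p_diff = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
        seq = parent.copy()
        change = rng.random(length) < p_diff
        n_change = int(change.sum())
        if n_change:
            # shift by 1..3 mod 4: uniform over the three other bases
            seq[change] = (seq[change] + rng.integers(1, 4, size=n_change)) % 4
        if node.is_leaf:
            records.append((node.name, "".join(_BASES[seq])))
        else:
            for child in node.children:
                evolve(seq, child)

    if tree.is_leaf:
        raise ValidationError("tree must have at least 2 leaves")
    for child in tree.children:
        evolve(root_seq, child)
    if tree.name is not None:  # a named root also emits its sequence
        records.append((tree.name, "".join(_BASES[root_seq])))
    return AlignedSequences(records)


def generate_histology(
    species: list[str],
    n_per_species: int = 4,
    occurrence: dict[str, float] | None = None,
    seed: int = 0,
) -> list[HistoProfile]:
    """Synthetic lesion-score profiles.

    Each category is present (score >= 1) with its configured occurrence
    probability; present lesions are mild/moderate/severe with probability
    0.5/0.3/0.2.
    """
    occurrence = occurrence or DEFAULT_LESION_OCCURRENCE
    profiles = []
    for sp in species:
        rng = stratum_rng(seed, sp, "histology")
        code = "".join(w[0] for w in sp.split()[:2])
        for i in range(n_per_species):
            scores = {}
            for cat in LESION_CATEGORIES:
                if rng.random() < occurrence[cat]:
                    scores[cat] = int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
                else:
                    scores[cat] = 0
            profiles.append(HistoProfile(f"{code}-h{i + 1}", sp, scores))
    return profiles
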