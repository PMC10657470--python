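"""Synthetic cohorts with the structure the analysis assumes.

The generator emulates a small trauma-survivor cohort profiled once by
stool metagenomics and followed at weeks 2, 8 and 12:

* compositional species profiles — per-subject log-normal intensities
  with species-specific base levels, zero-inflated by a per-sample
  detection quantile, closed to sum exactly 100 (percent scale);
* one stool sample per subject, reused at every week (the microbiome-
  stability design the longitudinal models rely on);
* a latent continuous severity response per subject-week,

      r_it = beta' c_i + sum_s gamma_s z_si + slope * week + b_i + e_it,

  where z_si is the z-scored arcsine-sqrt abundance of planted effector
  species s, b_i ~ N(0, sigma_b^2) a subject intercept and
  e_it ~ N(0, sigma_e^2) residual noise;
* the three instruments as maps of that one response: an affine,
  rounded, clipped PCL-5 raw score; an affine PROMIS t-score around
  mean 50; and a Binomial(12, logistic) somatic-symptom count;
* taxon-stratified pathway tables whose strata are fixed multiples of
  the contributing species' abundances, so community totals equal the
  stratum sums by construction.

Everything is driven by one ``numpy.random.default_rng(seed)``; a fixed
seed reproduces the cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CohortTable, PathwayAbundanceTable, SpeciesAbundanceTable
from .lmm import arcsine_sqrt

__all__ = ["SimulationConfig", "SyntheticCohort", "Truth", "simulate_cohort",
           "simulate_abundances", "simulate_outcomes", "simulate_pathways",
           "default_pathway_spec", "ARGININE_PATHWAYS"]

#: Arginine / ornithine / citrulline pathway set used for contribution tables.
ARGININE_PATHWAYS = (
    ("ARG-POLYAMINE-SYN", "superpathway of arginine and polyamine biosynthesis"),
    ("ARGSYNBSUB-PWY", "L-arginine biosynthesis II (acetyl cycle)"),
    ("ARGININE-SYN4-PWY", "L-ornithine de novo biosynthesis"),
    ("ARGSYN-PWY", "L-arginine biosynthesis I (via L-ornithine)"),
    ("CITRULBIO-PWY", "L-citrulline biosynthesis"),
)

_WEEKS = (2, 8, 12)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults mirror the target design: 51 subjects, ~200 detected
    species, 3 follow-up weeks, a dominant planted effector among five,
    subject-intercept SD 2 and residual SD 1 on the latent scale.
    """

    n_subjects: int = 51
    n_species: int = 200
    n_effectors: int = 5
    #: coefficients on z-scored arcsine-sqrt effector abundances; the first
    #: effector dominates so rank-recovery is well defined.
    gamma: tuple[float, ...] = (2.0, 0.5, 0.5, 0.5, 0.5)
    #: (age, male, bmi) coefficients on the latent response scale
    covariate_effects: tuple[float, float, float] = (0.01, 0.5, 0.02)
    sigma_b: float = 2.0
    sigma_e: float = 1.0
    timepoints: tuple[int, ...] = _WEEKS
    #: latent-response drift per week post-trauma (symptoms ease slightly)
    time_slope: float = -0.05
    #: per-sample fraction of species truncated to zero before closure
    sparsity: float = 0.25
    #: (mu, sigma) of the log-normal intensity noise around species base levels
    base_lognormal: tuple[float, float] = (0.0, 2.0)
    #: per-species base log-level SD (abundance rank structure)
    species_level_sd: float = 1.5
    #: log-level boost for effector species, keeping them prevalent
    effector_boost: float = 2.0
    # instrument maps of the latent response
    pcl5_base: float = 30.0
    pcl5_scale: float = 5.0
    promis_scale: float = 3.0
    somatic_scale: float = 0.4
    somatic_offset: float = -0.3
    #: (pathway_id, name, ((species, weight), ...)); None -> default arginine set
    pathway_spec: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_b < 0 or self.sigma_e < 0:
            raise ValueError("sigma_b and sigma_e must be nonnegative")
        if self.n_effectors > self.n_species:
            raise ValueError("n_effectors cannot exceed n_species")
        if len(self.gamma) != self.n_effectors:
            raise ValueError("gamma must have one coefficient per effector")
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must be in [0, 1)")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class Truth:
    """Planted generative quantities, for parameter-recovery checks."""

    effectors: list[str]
    gamma: np.ndarray
    sigma_b: float
    sigma_e: float
    b: pd.Series  # subject random intercepts
    response: pd.DataFrame  # subject_id, week, latent response
    effector_standardization: pd.DataFrame  # mean/sd of asin-sqrt abundance


@dataclass
class SyntheticCohort:
    species: SpeciesAbundanceTable
    pathways: PathwayAbundanceTable
    cohort: CohortTable
    outcomes: pd.DataFrame  # long: subject_id, week, pcl5_raw, promis_t, somatic_count
    truth: Truth = field(repr=False)


# ---------------------------------------------------------------------------
# species names and abundances
# ---------------------------------------------------------------------------

_PHYLA = ("Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria")


def _species_names(n: int) -> list[str]:
    """Deterministic synthetic lineages, MetaPhlAn style."""
    names = []
    for i in range(n):
        phylum = _PHYLA[i % len(_PHYLA)]
        genus = f"Genus{i // 4:03d}"
        species = f"{genus}_sp{i % 4 + 1}"
        names.append(
            f"k__Bacteria|p__{phylum}|c__ClassA|o__OrderA|f__Family{i // 8:03d}"
            f"|g__{genus}|s__{species}"
        )
    return names


def genus_of(lineage: str) -> str:
    for part in reversed(lineage.split("|")):
        if part.startswith("g__"):
            return part[3:]
    return "unclassified"


def species_of(lineage: str) -> str:
    for part in reversed(lineage.split("|")):
        if part.startswith("s__"):
            return part[3:]
    return lineage.split("|")[-1]


def _base_levels(config: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    levels = rng.normal(0.0, config.species_level_sd, size=config.n_species)
    effector_idx = rng.choice(config.n_species, size=config.n_effectors, replace=False)
    levels[effector_idx] += config.effector_boost
    return levels, effector_idx


def simulate_abundances(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> SpeciesAbundanceTable:
    """Zero-inflated compositional species table, closed to 100% per sample."""
    own_rng = rng is None
    rng = np.random.default_rng(config.seed) if own_rng else rng
    levels, _ = _base_levels(config, rng)
    return _abundances_from_levels(config, levels, rng)


def _abundances_from_levels(config: SimulationConfig, levels: np.ndarray,
                            rng: np.random.Generator) -> SpeciesAbundanceTable:
    mu, sigma = config.base_lognormal
    n, p = config.n_subjects, config.n_species
    log_intensity = mu + levels[None, :] + sigma * rng.standard_normal((n, p))
    intensity = np.exp(log_intensity)
    if config.sparsity > 0:
        thresh = np.quantile(intensity, config.sparsity, axis=1, keepdims=True)
        intensity = np.where(intensity < thresh, 0.0, intensity)
    closed = 100.0 * intensity / intensity.sum(axis=1, keepdims=True)
    sample_ids = [f"SAMP{i:03d}" for i in range(n)]
    df = pd.DataFrame(closed, index=pd.Index(sample_ids, name="sample_id"),
                      columns=_species_names(p))
    return SpeciesAbundanceTable(df)


# ---------------------------------------------------------------------------
# cohort covariates
# ---------------------------------------------------------------------------

_RACE_LEVELS = ("white", "black", "asian", "other")
_RACE_PROBS = (0.61, 0.25, 0.02, 0.12)


def _simulate_cohort_table(config: SimulationConfig, sample_ids: list[str],
                           rng: np.random.Generator) -> CohortTable:
    n = config.n_subjects
    df = pd.DataFrame(
        {
            "age": np.clip(rng.normal(50, 15, n), 18, 85).round(0),
            "sex": np.where(rng.random(n) < 0.51, "female", "male"),
            "bmi": np.clip(rng.normal(29, 6, n), 16, 55).round(1),
            "race_ethnicity": rng.choice(_RACE_LEVELS, size=n, p=_RACE_PROBS),
            # days from trauma to stool collection: median ~45, range ~5-182
            "days_since_trauma": np.clip(
                np.exp(rng.normal(np.log(45), 0.6, n)), 5, 182
            ).astype(int),
            "sample_id": sample_ids,
        },
        index=pd.Index([f"SUBJ{i:03d}" for i in range(n)], name="subject_id"),
    )
    return CohortTable(df)


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------


def simulate_outcomes(config: SimulationConfig, species: SpeciesAbundanceTable,
                      cohort: CohortTable, effectors: list[str],
                      rng: np.random.Generator) -> tuple[pd.DataFrame, Truth]:
    """Latent-response model mapped to the three instruments; truth recorded."""
    if list(cohort.data["sample_id"]) != species.sample_ids:
        raise ValueError("cohort sample ids are not aligned with the species table")
    props = species.to_proportions()
    trans = arcsine_sqrt(props[effectors].to_numpy())
    mean = trans.mean(axis=0)
    sd = trans.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (trans - mean) / sd
    gamma = np.asarray(config.gamma, dtype=float)
    microbe_part = z @ gamma

    beta_age, beta_male, beta_bmi = config.covariate_effects
    cov = cohort.data
    cov_part = (
        beta_age * (cov["age"].to_numpy(dtype=float) - 50.0)
        + beta_male * (cov["sex"].to_numpy() == "male")
        + beta_bmi * (cov["bmi"].to_numpy(dtype=float) - 29.0)
    )

    n = config.n_subjects
    b = rng.normal(0.0, config.sigma_b, n)
    rows = []
    for t in config.timepoints:
        eps = rng.normal(0.0, config.sigma_e, n)
        r = cov_part + microbe_part + config.time_slope * t + b + eps
        pcl5 = np.clip(np.rint(config.pcl5_base + config.pcl5_scale * r), 0, 80).astype(int)
        promis = 50.0 + config.promis_scale * r
        p_som = 1.0 / (1.0 + np.exp(-(config.somatic_scale * r + config.somatic_offset)))
        somatic = rng.binomial(12, p_som)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": cohort.subject_ids,
                    "week": t,
                    "pcl5_raw": pcl5,
                    "promis_t": promis,
                    "somatic_count": somatic,
                    "latent_response": r,
                }
            )
        )
    panel = pd.concat(rows, ignore_index=True)
    truth = Truth(
        effectors=list(effectors),
        gamma=gamma,
        sigma_b=config.sigma_b,
        sigma_e=config.sigma_e,
        b=pd.Series(b, index=cohort.subject_ids, name="b_true"),
        response=panel[["subject_id", "week", "latent_response"]].copy(),
        effector_standardization=pd.DataFrame(
            {"mean": mean, "sd": sd}, index=effectors
        ),
    )
    return panel.drop(columns="latent_response"), truth


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------


def default_pathway_spec(species_names: list[str], effectors: list[str]) -> tuple:
    """Arginine-pathway spec wired to planted effectors plus abundant bystanders.

    Each pathway gets 2-4 contributing species with fixed copy-number
    weights; effector species carry the planted signal into the
    functional profile.
    """
    pool = [s for s in species_names if s not in effectors]
    spec = []
    for k, (pwy_id, name) in enumerate(ARGININE_PATHWAYS):
        contributors = []
        contributors.append((effectors[k % len(effectors)], 1.0))
        contributors.append((pool[(3 * k) % len(pool)], 0.5))
        if k % 2 == 0:
            contributors.append((pool[(3 * k + 1) % len(pool)], 0.25))
        spec.append((pwy_id, name, tuple(contributors)))
    return tuple(spec)


def simulate_pathways(config: SimulationConfig, species: SpeciesAbundanceTable,
                      pathway_spec: tuple | None = None,
                      rng: np.random.Generator | None = None) -> PathwayAbundanceTable:
    """Stratified pathway table consistent with the species profiles.

    Stratum abundance = weight x species percent abundance (CPM-like
    arbitrary units); the community total is the exact sum of its
    strata, and UNMAPPED/UNINTEGRATED bookkeeping rows are appended.
    """
    spec = pathway_spec if pathway_spec is not None else config.pathway_spec
    if spec is None:
        raise ValueError("no pathway_spec provided")
    data: dict[str, np.ndarray] = {}
    known = set(species.species_names)
    for pwy_id, name, contributors in spec:
        total_key = f"{pwy_id}: {name}"
        strata = {}
        for sp, weight in contributors:
            if sp not in known:
                raise ValueError(f"pathway {pwy_id}: species {sp!r} not in species table")
            if weight < 0:
                raise ValueError(f"pathway {pwy_id}: negative weight for {sp!r}")
            taxon = f"g__{genus_of(sp)}.s__{species_of(sp)}"
            key = f"{total_key}|{taxon}"
            strata[key] = strata.get(key, 0.0) + weight * species.data[sp].to_numpy()
        data[total_key] = np.sum(list(strata.values()), axis=0)
        data.update(strata)
    n = len(species.sample_ids)
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    data["UNMAPPED"] = rng.uniform(1e3, 5e3, n)
    data["UNINTEGRATED"] = rng.uniform(1e4, 5e4, n)
    df = pd.DataFrame(data, index=pd.Index(species.sample_ids, name="sample_id"))
    return PathwayAbundanceTable(df)


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig | None = None, **kwargs) -> SyntheticCohort:
    """Generate species, pathways, covariates and outcomes for one cohort."""
    if config is None:
        config = SimulationConfig(**kwargs)
    rng = np.random.default_rng(config.seed)
    levels, effector_idx = _base_levels(config, rng)
    species = _abundances_from_levels(config, levels, rng)
    effectors = [species.species_names[i] for i in sorted(effector_idx)]
    # keep gamma aligned with the (sorted) effector order via the draw order
    order = np.argsort(effector_idx)
    gamma_sorted = tuple(np.asarray(config.gamma, dtype=float)[order])
    cohort = _simulate_cohort_table(config, species.sample_ids, rng)
    panel, truth = simulate_outcomes(
        config.with_(gamma=gamma_sorted), species, cohort, effectors, rng
    )
    spec = config.pathway_spec or default_pathway_spec(species.species_names, effectors)
    pathways = simulate_pathways(config, species, pathway_spec=spec, rng=rng)
    return SyntheticCohort(species=species, pathways=pathways, cohort=cohort,
                           outcomes=panel, truth=truth)
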