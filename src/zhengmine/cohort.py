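"""Synthetic CHD patient cohorts with latent TCM syndrome structure.

The generator emulates the statistical shape of a multi-centre CHD in-patient
dataset: binary four-diagnostic symptom indicators, a standardized clinical
biomarker panel, and binary syndrome labels. Each patient carries latent
binary syndrome statuses drawn at configured prevalences; a symptom mapped to
a syndrome fires at a lifted rate when that syndrome is present, and a
biomarker linked to a syndrome has its (standardized) mean shifted.

Defaults follow the reference cohort: n=411 patients, qi-deficiency
prevalence 225/411, phlegm-blood-stasis prevalence 69/411, 69 symptoms,
90 biomarkers of which 8 are qi-shifted and 6 phlegm-shifted by one
standard deviation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import vocab

SYMPTOM_PREFIX = "sym_"
BIOMARKER_PREFIX = "bio_"
LABEL_PREFIX = "lab_"


class ConfigurationError(ValueError):
    """Invalid generator or pipeline configuration."""


class CohortParseError(ValueError):
    """Malformed cohort CSV."""


@dataclass(frozen=True)
class BiomarkerSpec:
    """One biomarker: baseline Normal(mean, sd) plus per-syndrome mean shifts."""

    name: str
    mean: float = 0.0
    sd: float = 1.0
    shifts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ConfigurationError(
                f"biomarker {self.name!r}: sd must be > 0, got {self.sd}"
            )


def default_biomarker_specs(shift: float = 1.0) -> list[BiomarkerSpec]:
    """The 90-biomarker panel, standardized, with one-sd syndrome shifts.

    The 8 qi-mode parameters are shifted under qi deficiency and the 6
    phlegm-mode parameters under phlegm-blood stasis; hs-CRP belongs to both
    modes and is shifted under either syndrome.
    """
    specs = []
    for name in vocab.BIOMARKERS:
        shifts: dict[str, float] = {}
        if name in vocab.QI_MODE_BIOMARKERS:
            shifts["qi deficiency"] = shift
        if name in vocab.PHLEGM_MODE_BIOMARKERS:
            shifts[vocab.PHLEGM_BLOOD_STASIS] = shift
        specs.append(BiomarkerSpec(name=name, shifts=shifts))
    return specs


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 411
    syndrome_prevalences: dict[str, float] = field(
        default_factory=lambda: {
            "qi deficiency": 225 / 411,
            vocab.PHLEGM_BLOOD_STASIS: 69 / 411,
        }
    )
    symptom_names: tuple[str, ...] = vocab.SYMPTOMS
    symptom_base_rate: float = 0.10
    symptom_lift_rate: float = 0.60
    biomarker_specs: tuple[BiomarkerSpec, ...] = tuple(default_biomarker_specs())
    n_noise_biomarkers: int = 0
    syndrome_correlation: float = 0.0
    missing_rate: float = 0.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError(
                f"n_patients must be >= 1, got {self.n_patients}"
            )
        for name, p in self.syndrome_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"prevalence of {name!r} must be in [0, 1], got {p}"
                )
        for p, what in (
            (self.symptom_base_rate, "symptom_base_rate"),
            (self.symptom_lift_rate, "symptom_lift_rate"),
            (self.missing_rate, "missing_rate"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{what} must be in [0, 1], got {p}")
        if not -1.0 < self.syndrome_correlation < 1.0:
            raise ConfigurationError(
                "syndrome_correlation must be in (-1, 1), "
                f"got {self.syndrome_correlation}"
            )
        if self.n_noise_biomarkers < 0:
            raise ConfigurationError("n_noise_biomarkers must be >= 0")
        names = [s.name for s in self.biomarker_specs]
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate biomarker names in specs")


@dataclass
class Cohort:
    """Row-aligned patient tables: binary symptoms, numeric biomarkers,
    binary syndrome labels."""

    patient_ids: list[str]
    symptoms: pd.DataFrame
    biomarkers: pd.DataFrame
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.patient_ids)
        if len(set(self.patient_ids)) != n:
            raise ValueError("duplicate patient ids")
        for tab, what in (
            (self.symptoms, "symptoms"),
            (self.biomarkers, "biomarkers"),
            (self.labels, "labels"),
        ):
            if len(tab) != n:
                raise ValueError(f"{what} table not row-aligned with patient ids")
            if tab.columns.duplicated().any():
                raise ValueError(f"duplicate column names in {what}")
        for tab, what in ((self.symptoms, "symptoms"), (self.labels, "labels")):
            if len(tab.columns) and not tab.isin([0, 1]).all().all():
                raise ValueError(f"non-binary value in {what}")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def equals(self, other: "Cohort") -> bool:
        return (
            self.patient_ids == other.patient_ids
            and self.symptoms.equals(other.symptoms)
            and self.biomarkers.equals(other.biomarkers)
            and self.labels.equals(other.labels)
        )


def _draw_syndromes(
    config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Latent syndrome statuses; independent Bernoullis, or a Gaussian copula
    with equicorrelation when syndrome_correlation != 0."""
    names = list(config.syndrome_prevalences)
    n, k = config.n_patients, len(names)
    prevalences = np.array([config.syndrome_prevalences[s] for s in names])
    if k == 0:
        return pd.DataFrame(index=range(n))
    if config.syndrome_correlation == 0.0 or k == 1:
        draws = rng.random((n, k)) < prevalences
    else:
        rho = config.syndrome_correlation
        cov = np.full((k, k), rho)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
        draws = stats.norm.cdf(z) < prevalences
    return pd.DataFrame(draws.astype(np.int8), columns=names)


def generate_cohort(
    config: GeneratorConfig,
    syndrome_map: dict[str, str] | None = None,
) -> Cohort:
    """Generate a synthetic cohort.

    Parameters
    ----------
    config
        Sample size, prevalences, symptom rates, biomarker specs, seed.
    syndrome_map
        Symptom name -> syndrome name. A mapped symptom fires with
        probability ``symptom_lift_rate`` when its syndrome is present and
        ``symptom_base_rate`` otherwise; unmapped symptoms always fire at the
        base rate. Defaults to the published core-symptom assignment with the
        phlegm-turbid and blood-stasis groups lifting phlegm-blood stasis.
    """
    if syndrome_map is None:
        syndrome_map = vocab.GENERATOR_SYNDROME_MAP
    unknown = set(syndrome_map) - set(config.symptom_names)
    if unknown:
        raise ConfigurationError(
            f"syndrome_map refers to unknown symptoms: {sorted(unknown)}"
        )
    rng = np.random.default_rng(config.random_seed)
    n = config.n_patients

    labels = _draw_syndromes(config, rng)

    rates = np.full((n, len(config.symptom_names)), config.symptom_base_rate)
    for j, sym in enumerate(config.symptom_names):
        syndrome = syndrome_map.get(sym)
        if syndrome is not None and syndrome in labels.columns:
            present = labels[syndrome].to_numpy(bool)
            rates[present, j] = config.symptom_lift_rate
    symptoms = pd.DataFrame(
        (rng.random(rates.shape) < rates).astype(np.int8),
        columns=list(config.symptom_names),
    )

    cols = {}
    for spec in config.biomarker_specs:
        mean = np.full(n, spec.mean, dtype=float)
        for syndrome, delta in spec.shifts.items():
            if syndrome in labels.columns:
                mean += delta * spec.sd * labels[syndrome].to_numpy(float)
        cols[spec.name] = rng.normal(mean, spec.sd)
    for i in range(config.n_noise_biomarkers):
        cols[f"noise_{i + 1:02d}"] = rng.normal(0.0, 1.0, size=n)
    biomarkers = pd.DataFrame(cols, index=range(n))

    if config.missing_rate > 0 and len(biomarkers.columns):
        mask = rng.random(biomarkers.shape) < config.missing_rate
        biomarkers = biomarkers.mask(mask)

    patient_ids = [f"P{i + 1:04d}" for i in range(n)]
    return Cohort(patient_ids, symptoms, biomarkers, labels)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as UTF-8 CSV; `patient_id` plus prefixed columns."""
    frame = pd.concat(
        [
            pd.DataFrame({"patient_id": cohort.patient_ids}),
            cohort.symptoms.add_prefix(SYMPTOM_PREFIX),
            cohort.biomarkers.add_prefix(BIOMARKER_PREFIX),
            cohort.labels.add_prefix(LABEL_PREFIX),
        ],
        axis=1,
    )
    frame.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort`, validating the
    binary tables cell by cell."""
    try:
        frame = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise CohortParseError(f"{path}: empty cohort file") from exc
    except (pd.errors.ParserError, OSError) as exc:
        raise CohortParseError(f"{path}: {exc}") from exc
    if "patient_id" not in frame.columns:
        raise CohortParseError(f"{path}: missing patient_id column")

    def split(prefix: str) -> pd.DataFrame:
        cols = [c for c in frame.columns if c.startswith(prefix)]
        sub = frame[cols].copy()
        sub.columns = [c[len(prefix):] for c in cols]
        return sub

    symptoms, biomarkers, labels = (
        split(SYMPTOM_PREFIX), split(BIOMARKER_PREFIX), split(LABEL_PREFIX)
    )
    for tab, prefix in ((symptoms, SYMPTOM_PREFIX), (labels, LABEL_PREFIX)):
        bad = ~tab.isin([0, 1])
        if len(tab.columns) and bad.any().any():
            col = bad.any()[bad.any()].index[0]
            row = int(bad[col].idxmax())
            raise CohortParseError(
                f"{path}: non-binary value {tab.at[row, col]!r} in column "
                f"{prefix}{col!r}, row {row}"
            )
        tab[tab.columns] = tab.astype(np.int8)
    return Cohort(
        frame["patient_id"].astype(str).tolist(), symptoms, biomarkers, labels
    )
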