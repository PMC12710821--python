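"""Synthetic cohorts of parcel timeseries with planted hemispheric asymmetry.

The generator emulates the kind of resting-state cohort the analysis is
designed for: each subject has an Edinburgh Handedness Inventory (EHI)
score drawn from a J-shaped population distribution (about 90% dextral),
and two hemispheres of parcel timeseries drawn from block-structured
correlation matrices.  Hemispheric asymmetry is planted as an LH-minus-RH
offset on selected network-pair blocks (by default the language<->default
mode, language<->frontoparietal and within-default-mode blocks), with the
offset magnitude scaled by a piecewise-linear function of EHI that rises
up to a breakpoint and is flat above it — strongly right-handed subjects
carry the full planted asymmetry, sinistral subjects much less.

Positive definiteness is structural: the parcel-level correlation matrix
is assembled as ``Z B Z'`` plus a positive diagonal, where ``B`` is a
network-level Gram matrix (checked by Cholesky) and ``Z`` the
parcel->network indicator, i.e. a network-factor-plus-diagonal model.
Offsets perturb ``B``, never raw matrix entries.

All generator defaults are stand-ins: no public generative model exists
for these data, and the defaults were fixed once from the study-design
quantities (population dextral fraction, asymmetric network pairs,
EHI-distance breakpoint at 75) before any downstream result was computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from hemiconn.connectome import ParcelAtlas

__all__ = [
    "EhiModel",
    "DistanceModel",
    "CohortSpec",
    "SyntheticSubject",
    "Cohort",
    "CovarianceConstructionError",
    "default_networks",
    "DEFAULT_ASYMMETRY_MAP",
    "sample_ehi",
    "handedness_from_ehi",
    "asymmetry_scale",
    "build_hemisphere_covariance",
    "simulate_timeseries",
    "sample_distances",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

EHI_MIN, EHI_MAX = -100.0, 100.0

#: Default planted LH-minus-RH block offsets (Fisher-Z-scale correlation units).
DEFAULT_ASYMMETRY_MAP: Mapping[tuple[str, str], float] = {
    ("DMN", "LN"): 0.15,
    ("FPN", "LN"): 0.15,
    ("DMN", "DMN"): 0.10,
}

#: Relative sizes used to allocate parcels over the eight kept networks.
_NETWORK_FRACTIONS = (
    ("Visual", 0.25),
    ("SMN", 0.17),
    ("DMN", 0.20),
    ("FPN", 0.13),
    ("CON", 0.10),
    ("DAN", 0.05),
    ("LN", 0.07),
    ("AudN", 0.03),
)


class CovarianceConstructionError(ValueError):
    """Requested block offsets do not admit a positive-definite matrix."""


def default_networks(parcels_per_hemi: int) -> list[tuple[str, int]]:
    """Allocate parcels over the eight canonical networks, largest remainder.

    Requires at least 16 parcels per hemisphere so every network gets >= 2
    parcels (a within-network block needs two parcels to contain an edge).
    """
    if parcels_per_hemi < 16:
        raise ValueError("default network allocation needs >= 16 parcels per hemisphere")
    raw = [(name, frac * parcels_per_hemi) for name, frac in _NETWORK_FRACTIONS]
    counts = {name: max(2, int(np.floor(x))) for name, x in raw}
    remainder = parcels_per_hemi - sum(counts.values())
    # distribute leftover parcels by largest fractional part
    order = sorted(raw, key=lambda t: t[1] - np.floor(t[1]), reverse=True)
    i = 0
    while remainder > 0:
        counts[order[i % len(order)][0]] += 1
        remainder -= 1
        i += 1
    while remainder < 0:  # only possible at very small P where the min-2 rule overshoots
        name = max(counts, key=counts.get)
        counts[name] -= 1
        remainder += 1
    return [(name, counts[name]) for name, _ in _NETWORK_FRACTIONS]


@dataclass(frozen=True)
class EhiModel:
    """Two-component J-shaped EHI sampler.

    A dextral component (truncated normal on (0, 100], concentrated near
    +80) carries ``dextral_mass`` of the probability; the complementary
    non-dextral component is a broad truncated normal on [-100, 0].  The
    truncation boundaries make the expected dextral fraction equal the
    mass parameter exactly.
    """

    dextral_mass: float = 0.90
    dextral_loc: float = 80.0
    dextral_scale: float = 18.0
    sinistral_loc: float = -40.0
    sinistral_scale: float = 55.0

    def validate(self) -> None:
        if not 0.0 <= self.dextral_mass <= 1.0:
            raise ValueError(f"dextral_mass must lie in [0, 1], got {self.dextral_mass}")
        if self.dextral_scale <= 0 or self.sinistral_scale <= 0:
            raise ValueError("component scales must be positive")


@dataclass(frozen=True)
class DistanceModel:
    """Piecewise-linear link from EHI to hemispheric asymmetry/distance.

    ``raw(ehi) = slope_below * min(ehi, breakpoint)
               + slope_above * max(ehi - breakpoint, 0)``

    ``intercept + raw(ehi) + N(0, noise_sd)`` is the realized hemisphere
    distance (LD1_dist units); the covariance builder instead uses ``raw``
    rescaled to [0, 1] over the EHI range as a noiseless asymmetry scale.
    """

    slope_below: float = 0.01
    breakpoint: float = 75.0
    slope_above: float = 0.0
    noise_sd: float = 2.0
    intercept: float = 8.0

    def validate(self) -> None:
        if not EHI_MIN <= self.breakpoint <= EHI_MAX:
            raise ValueError("breakpoint must lie within the EHI range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def raw(self, ehi: np.ndarray | float) -> np.ndarray | float:
        e = np.asarray(ehi, dtype=float)
        out = self.slope_below * np.minimum(e, self.breakpoint)
        out = out + self.slope_above * np.maximum(e - self.breakpoint, 0.0)
        return out if out.ndim else float(out)

    def mean_distance(self, ehi: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.raw(ehi)


def asymmetry_scale(model: DistanceModel, ehi: np.ndarray | float) -> np.ndarray | float:
    """The piecewise-linear link rescaled to [0, 1] over the EHI range."""
    lo = model.raw(EHI_MIN)
    hi = model.raw(EHI_MAX)
    if hi <= lo:
        return np.ones_like(np.asarray(ehi, dtype=float)) if np.ndim(ehi) else 1.0
    s = (model.raw(ehi) - lo) / (hi - lo)
    return np.clip(s, 0.0, 1.0)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort (including its seed)."""

    n_subjects: int = 200
    parcels_per_hemi: int = 180
    timepoints: int = 300
    networks: tuple[tuple[str, int], ...] | None = None
    asymmetry_map: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ASYMMETRY_MAP)
    )
    within_corr: float = 0.35
    between_corr: float = 0.10
    ehi_model: EhiModel = field(default_factory=EhiModel)
    distance_model: DistanceModel = field(default_factory=DistanceModel)
    seed: int = 0

    @classmethod
    def desk_scale(cls, **overrides) -> "CohortSpec":
        """The reduced-scale study conditions used throughout tests and docs."""
        defaults = dict(n_subjects=200, parcels_per_hemi=40, timepoints=300)
        defaults.update(overrides)
        return cls(**defaults)

    def resolved_networks(self) -> tuple[tuple[str, int], ...]:
        if self.networks is not None:
            return tuple((str(a), int(b)) for a, b in self.networks)
        return tuple(default_networks(self.parcels_per_hemi))

    def atlas(self) -> ParcelAtlas:
        return ParcelAtlas.from_networks(self.resolved_networks())

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.parcels_per_hemi <= 0 or self.timepoints <= 0:
            raise ValueError("all counts must be positive")
        nets = self.resolved_networks()
        total = sum(c for _, c in nets)
        if total != self.parcels_per_hemi:
            raise ValueError(
                f"network parcel counts sum to {total}, expected {self.parcels_per_hemi}"
            )
        labels = {name for name, _ in nets}
        for pair in self.asymmetry_map:
            a, b = pair
            if a not in labels or b not in labels:
                raise ValueError(f"asymmetry_map references unknown network pair {pair}")
        self.ehi_model.validate()
        self.distance_model.validate()
        # PD feasibility at the strongest asymmetry
        for hemi in ("LH", "RH"):
            build_hemisphere_covariance(self, EHI_MAX, hemi)


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    ehi: float
    handedness: str
    timeseries_lh: np.ndarray
    timeseries_rh: np.ndarray

    def __post_init__(self) -> None:
        if self.handedness != handedness_from_ehi(self.ehi):
            raise ValueError("handedness inconsistent with EHI under the <=0 cutoff")


@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    subjects: tuple[SyntheticSubject, ...]
    atlas: ParcelAtlas

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "ehi": [s.ehi for s in self.subjects],
                "handedness": [s.handedness for s in self.subjects],
            }
        )


def handedness_from_ehi(ehi: float) -> str:
    """Dextral iff EHI > 0; EHI <= 0 is sinistral (the study's cutoff)."""
    return "dextral" if ehi > 0 else "sinistral"


def sample_ehi(
    n: int,
    ehi_model: EhiModel | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` EHI scores from the J-shaped two-component mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    model = ehi_model if ehi_model is not None else EhiModel()
    model.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    is_dextral = rng.random(n) < model.dextral_mass
    out = np.empty(n)
    a_d = (0.0 - model.dextral_loc) / model.dextral_scale
    b_d = (EHI_MAX - model.dextral_loc) / model.dextral_scale
    a_s = (EHI_MIN - model.sinistral_loc) / model.sinistral_scale
    b_s = (0.0 - model.sinistral_loc) / model.sinistral_scale
    n_d = int(is_dextral.sum())
    if n_d:
        out[is_dextral] = stats.truncnorm.rvs(
            a_d, b_d, loc=model.dextral_loc, scale=model.dextral_scale,
            size=n_d, random_state=rng,
        )
    if n - n_d:
        out[~is_dextral] = stats.truncnorm.rvs(
            a_s, b_s, loc=model.sinistral_loc, scale=model.sinistral_scale,
            size=n - n_d, random_state=rng,
        )
    return np.clip(out, EHI_MIN, EHI_MAX)


def _network_gram(spec: CohortSpec, ehi: float, hemi: str) -> np.ndarray:
    nets = spec.resolved_networks()
    labels = [name for name, _ in nets]
    k = len(labels)
    b = np.full((k, k), spec.between_corr)
    np.fill_diagonal(b, spec.within_corr)
    if hemi == "LH":
        scale = float(asymmetry_scale(spec.distance_model, ehi))
        for (na, nb), offset in spec.asymmetry_map.items():
            ia, ib = labels.index(na), labels.index(nb)
            b[ia, ib] += offset * scale
            if ia != ib:
                b[ib, ia] += offset * scale
    elif hemi != "RH":
        raise ValueError(f"hemi must be 'LH' or 'RH', got {hemi!r}")
    return b


def build_hemisphere_covariance(spec: CohortSpec, ehi: float, hemi: str) -> np.ndarray:
    """Block-structured parcel correlation matrix for one hemisphere.

    The network Gram matrix ``B`` holds within-network correlations on its
    diagonal and between-network correlations off it; for the LH the
    network pairs named in ``asymmetry_map`` are offset by
    ``offset * asymmetry_scale(ehi)``.  The parcel matrix is ``Z B Z'``
    with unit diagonal, positive definite whenever ``B`` is PSD with
    diagonal < 1 (checked; violations raise
    :class:`CovarianceConstructionError`).
    """
    nets = spec.resolved_networks()
    b = _network_gram(spec, ehi, hemi)
    if np.any(np.diag(b) >= 1.0):
        raise CovarianceConstructionError("within-network correlation must stay below 1")
    eigmin = float(np.linalg.eigvalsh(b).min())
    if eigmin <= -1e-12:
        raise CovarianceConstructionError(
            f"network Gram matrix is not PSD (min eigenvalue {eigmin:.3g}); "
            "reduce the planted offsets"
        )
    z = np.zeros((spec.parcels_per_hemi, len(nets)))
    start = 0
    for col, (_, count) in enumerate(nets):
        z[start : start + count, col] = 1.0
        start += count
    sigma = z @ b @ z.T
    np.fill_diagonal(sigma, 1.0)
    return sigma


def simulate_timeseries(
    cov: np.ndarray, timepoints: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Sample a (parcels x timepoints) Gaussian timeseries with covariance ``cov``."""
    cov = np.asarray(cov, dtype=float)
    p = cov.shape[0]
    if timepoints < p + 2:
        warnings.warn(
            f"timepoints={timepoints} < parcels+2={p + 2}: sample correlation "
            "will be rank-deficient",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise CovarianceConstructionError("covariance is not positive definite") from exc
    return chol @ rng.standard_normal((p, timepoints))


def sample_distances(
    ehi: np.ndarray,
    model: DistanceModel | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Realized hemisphere distances: piecewise mean plus Gaussian noise."""
    model = model if model is not None else DistanceModel()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ehi = np.asarray(ehi, dtype=float)
    return model.mean_distance(ehi) + rng.normal(0.0, model.noise_sd, size=ehi.shape)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort: EHI scores, handedness, and both timeseries.

    Deterministic in ``spec`` (including ``spec.seed``): per-subject random
    streams are spawned from a single seed sequence.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    ehi_ss, ts_ss = root.spawn(2)
    ehi = sample_ehi(spec.n_subjects, spec.ehi_model, np.random.default_rng(ehi_ss))
    subject_streams = ts_ss.spawn(spec.n_subjects)
    width = max(3, len(str(spec.n_subjects)))
    subjects = []
    for i in range(spec.n_subjects):
        rng = np.random.default_rng(subject_streams[i])
        cov_lh = build_hemisphere_covariance(spec, float(ehi[i]), "LH")
        cov_rh = build_hemisphere_covariance(spec, float(ehi[i]), "RH")
        ts_lh = simulate_timeseries(cov_lh, spec.timepoints, rng)
        ts_rh = simulate_timeseries(cov_rh, spec.timepoints, rng)
        subjects.append(
            SyntheticSubject(
                subject_id=f"sub-{i + 1:0{width}d}",
                ehi=float(ehi[i]),
                handedness=handedness_from_ehi(float(ehi[i])),
                timeseries_lh=ts_lh,
                timeseries_rh=ts_rh,
            )
        )
    return Cohort(spec=spec, subjects=tuple(subjects), atlas=spec.atlas())


def _spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "n_subjects": spec.n_subjects,
        "parcels_per_hemi": spec.parcels_per_hemi,
        "timepoints": spec.timepoints,
        "networks": [list(t) for t in spec.resolved_networks()],
        "asymmetry_map": {f"{a}|{b}": float(v) for (a, b), v in spec.asymmetry_map.items()},
        "within_corr": spec.within_corr,
        "between_corr": spec.between_corr,
        "ehi_model": vars(spec.ehi_model).copy(),
        "distance_model": vars(spec.distance_model).copy(),
        "seed": spec.seed,
    }


def spec_from_dict(data: Mapping) -> CohortSpec:
    data = dict(data)
    if "networks" in data and data["networks"] is not None:
        data["networks"] = tuple((str(a), int(b)) for a, b in data["networks"])
    if "asymmetry_map" in data:
        data["asymmetry_map"] = {
            (tuple(k.split("|")) if isinstance(k, str) else tuple(k)): float(v)
            for k, v in data["asymmetry_map"].items()
        }
    if "ehi_model" in data and isinstance(data["ehi_model"], Mapping):
        data["ehi_model"] = EhiModel(**data["ehi_model"])
    if "distance_model" in data and isinstance(data["distance_model"], Mapping):
        data["distance_model"] = DistanceModel(**data["distance_model"])
    return CohortSpec(**data)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write subjects.tsv, per-subject timeseries TSVs, the parcel table, and
    cohort_spec.yaml (full provenance including the seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.metadata.to_csv(out / "subjects.tsv", sep="\t", index=False)
    cohort.atlas.to_tsv(out / "parcels.tsv")
    for s in cohort.subjects:
        np.savetxt(out / f"{s.subject_id}_LH.tsv", s.timeseries_lh, delimiter="\t")
        np.savetxt(out / f"{s.subject_id}_RH.tsv", s.timeseries_rh, delimiter="\t")
    (out / "cohort_spec.yaml").write_text(
        yaml.safe_dump(_spec_to_dict(cohort.spec), sort_keys=False)
    )


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`."""
    src = Path(in_dir)
    spec = spec_from_dict(yaml.safe_load((src / "cohort_spec.yaml").read_text()))
    meta = pd.read_csv(src / "subjects.tsv", sep="\t")
    atlas = ParcelAtlas.from_tsv(src / "parcels.tsv")
    subjects = []
    for row in meta.itertuples(index=False):
        subjects.append(
            SyntheticSubject(
                subject_id=str(row.subject_id),
                ehi=float(row.ehi),
                handedness=str(row.handedness),
                timeseries_lh=np.loadtxt(src / f"{row.subject_id}_LH.tsv", delimiter="\t"),
                timeseries_rh=np.loadtxt(src / f"{row.subject_id}_RH.tsv", delimiter="\t"),
            )
        )
    return Cohort(spec=spec, subjects=tuple(subjects), atlas=atlas)
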