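"""Connectivity matrices, parcel atlases, and connectome feature vectors.

A parcellation with ``P`` parcels per hemisphere yields a ``2P x 2P``
Fisher-Z connectivity matrix per subject (LH parcels occupy indices
``0..P-1``, RH parcels ``P..2P-1``).  Three feature sets are extracted
from it:

* hemiconnectome (HC-LH / HC-RH): the ``P(P-1)/2`` within-hemisphere
  connections of one hemisphere, ordered by the upper triangle (row-major,
  ``i < j``) of within-hemisphere parcel indices.  The two hemiconnectomes
  use the same ordering over homologous parcels, so homologous connections
  share a feature index.
* transconnectome (TC): the ``P^2 - P`` heterotopic interhemispheric
  connections.  Homotopic pairs (a parcel with its own homologue) are
  excluded by convention, which makes the full-connectome count
  ``2 * P(P-1)/2 + (P^2 - P)`` (64,440 at P=180).
* full connectome (FC): HC-LH ++ HC-RH ++ TC.

At P=180 the hemiconnectome has 16,110 features and the full connectome
64,440.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParcelAtlas",
    "ConnectivityMatrix",
    "FeatureVectorSet",
    "COLE_ANTICEVIC_LABELS",
    "DEFAULT_MERGE_RULES",
    "DEFAULT_DROP_RULES",
    "pearson_matrix",
    "fisher_z",
    "feature_pairs",
    "extract_features",
    "features_to_matrix",
    "hemi_mask_to_matrix",
    "symmetrize_networks",
    "merge_and_drop_networks",
    "subject_connectivity",
    "hc_feature_count",
    "tc_feature_count",
    "fc_feature_count",
]

FISHER_CLIP = 1e-7

#: The 12 Cole-Anticevic resting-state networks over the Glasser parcels.
COLE_ANTICEVIC_LABELS = (
    "VIS1", "VIS2", "SMN", "CON", "DAN", "LN",
    "FPN", "AudN", "DMN", "PMN", "VMN", "OAN",
)

#: Default merging: the two visual networks become one.
DEFAULT_MERGE_RULES: Mapping[str, tuple[str, ...]] = {"Visual": ("VIS1", "VIS2")}

#: Default drops: the three smallest networks are excluded from enrichment.
DEFAULT_DROP_RULES: tuple[str, ...] = ("PMN", "VMN", "OAN")


class ZeroVarianceParcelError(ValueError):
    """A parcel timecourse is constant; its correlations are undefined."""


def hc_feature_count(p: int) -> int:
    """Number of hemiconnectome features for P parcels per hemisphere."""
    return p * (p - 1) // 2


def tc_feature_count(p: int) -> int:
    """Number of transconnectome (heterotopic interhemispheric) features."""
    return p * p - p


def fc_feature_count(p: int) -> int:
    """Number of full-connectome features (homotopic pairs excluded)."""
    return 2 * hc_feature_count(p) + tc_feature_count(p)


@dataclass(frozen=True)
class ParcelAtlas:
    """Parcel identities, hemisphere membership, homology and network labels.

    Parameters
    ----------
    parcel_ids
        2P parcel identifiers, LH parcels first.
    network_raw
        Per-parcel network label as originally assigned (may be
        asymmetric between homologues).
    network_sym, kept_networks
        Filled by :func:`symmetrize_networks` and
        :func:`merge_and_drop_networks`.

    The homologue mapping is positional: LH parcel ``i`` pairs with RH
    parcel ``P + i``.
    """

    parcel_ids: tuple[str, ...]
    network_raw: tuple[str, ...]
    network_sym: tuple[str, ...] | None = None
    kept_networks: tuple[str, ...] | None = None
    excluded: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.parcel_ids)
        if n % 2 != 0 or n == 0:
            raise ValueError("atlas must contain an even, positive parcel count")
        if len(self.network_raw) != n:
            raise ValueError("network_raw length must match parcel count")
        if len(set(self.parcel_ids)) != n:
            raise ValueError("parcel ids must be unique")

    @property
    def parcels_per_hemi(self) -> int:
        return len(self.parcel_ids) // 2

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def hemisphere(self) -> np.ndarray:
        p = self.parcels_per_hemi
        return np.array(["LH"] * p + ["RH"] * p)

    def homologue(self, index: int) -> int:
        """Index of the homologous parcel in the other hemisphere."""
        p = self.parcels_per_hemi
        return index + p if index < p else index - p

    @property
    def networks(self) -> np.ndarray:
        """Effective per-parcel labels: symmetrized if available, else raw."""
        labels = self.network_sym if self.network_sym is not None else self.network_raw
        return np.array(labels)

    @classmethod
    def from_networks(cls, networks: Sequence[tuple[str, int]]) -> "ParcelAtlas":
        """Build a symmetric atlas from (label, parcels-per-hemisphere) pairs."""
        labels: list[str] = []
        for name, count in networks:
            if count <= 0:
                raise ValueError(f"network {name!r} has non-positive size {count}")
            labels.extend([name] * count)
        p = len(labels)
        ids = tuple(f"L{i + 1:03d}" for i in range(p)) + tuple(
            f"R{i + 1:03d}" for i in range(p)
        )
        raw = tuple(labels) * 2
        atlas = cls(parcel_ids=ids, network_raw=raw)
        atlas, _ = symmetrize_networks(atlas)
        return merge_and_drop_networks(atlas, merge_rules={}, drop_rules=())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ParcelAtlas":
        """Read a parcel table (parcel_id, hemisphere, homologue_id, network).

        Rows are reordered so LH parcels come first and RH parcels follow in
        homologue order.
        """
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"parcel_id", "hemisphere", "homologue_id", "network"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"parcel table missing columns: {sorted(missing)}")
        lh = df[df["hemisphere"] == "LH"].reset_index(drop=True)
        rh = df[df["hemisphere"] == "RH"].set_index("parcel_id")
        if len(lh) * 2 != len(df):
            raise ValueError("hemispheres have unequal parcel counts")
        homol = lh["homologue_id"].tolist()
        if sorted(homol) != sorted(rh.index.tolist()):
            raise ValueError("homologue mapping is not a perfect matching")
        rh_ordered = rh.loc[homol]
        ids = tuple(lh["parcel_id"]) + tuple(rh_ordered.index)
        raw = tuple(lh["network"]) + tuple(rh_ordered["network"])
        return cls(parcel_ids=ids, network_raw=raw)

    def to_tsv(self, path: str | Path) -> None:
        p = self.parcels_per_hemi
        homologues = [self.parcel_ids[self.homologue(i)] for i in range(2 * p)]
        pd.DataFrame(
            {
                "parcel_id": self.parcel_ids,
                "hemisphere": self.hemisphere,
                "homologue_id": homologues,
                "network": self.network_raw,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Per-subject square Fisher-Z connectivity matrix."""

    subject_id: str
    values: np.ndarray
    convention_tag: str = "fisher-z upper-triangle row-major, LH block first"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class FeatureVectorSet:
    """A connectome feature vector plus its index -> parcel-pair map."""

    kind: str
    vector: np.ndarray
    index_map: np.ndarray  # (n_features, 2) global parcel indices

    def __len__(self) -> int:
        return len(self.vector)


def pearson_matrix(
    timeseries_lh: np.ndarray, timeseries_rh: np.ndarray
) -> np.ndarray:
    """Pairwise Pearson correlation between all parcels of both hemispheres.

    Parameters
    ----------
    timeseries_lh, timeseries_rh
        ``(P, T)`` arrays of parcel timecourses, equal shapes, ``T >= 3``.

    Returns
    -------
    ``(2P, 2P)`` symmetric correlation matrix with unit diagonal; LH
    parcels occupy rows/columns ``0..P-1``.
    """
    lh = np.asarray(timeseries_lh, dtype=float)
    rh = np.asarray(timeseries_rh, dtype=float)
    if lh.shape != rh.shape:
        raise ValueError("hemisphere timeseries must have identical shapes")
    if lh.ndim != 2 or lh.shape[1] < 3:
        raise ValueError("need (P, T) timeseries with at least 3 timepoints")
    stacked = np.vstack([lh, rh])
    sd = stacked.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ZeroVarianceParcelError(
            f"constant timecourse for parcel index(es) {dead.tolist()}"
        )
    r = np.corrcoef(stacked)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2.0


def fisher_z(r_matrix: np.ndarray, clip: float = FISHER_CLIP) -> np.ndarray:
    """Fisher-Z (atanh) transform of a correlation matrix.

    ``|r|`` is clipped to ``1 - clip`` before the transform so that
    correlations of exactly +/-1 map to large finite values; the diagonal
    is set to 0.
    """
    r = np.asarray(r_matrix, dtype=float)
    if np.nanmax(np.abs(r)) > 1 + 1e-12:
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -1.0 + clip, 1.0 - clip))
    if z.ndim == 2 and z.shape[0] == z.shape[1]:
        np.fill_diagonal(z, 0.0)
    return z


def subject_connectivity(
    subject_id: str, timeseries_lh: np.ndarray, timeseries_rh: np.ndarray
) -> ConnectivityMatrix:
    """Pearson + Fisher-Z pipeline for one subject."""
    return ConnectivityMatrix(
        subject_id=subject_id,
        values=fisher_z(pearson_matrix(timeseries_lh, timeseries_rh)),
    )


def feature_pairs(p: int, kind: str) -> np.ndarray:
    """Canonical (i, j) global parcel-index pairs for a feature kind.

    Hemiconnectome ordering is the upper triangle of the within-hemisphere
    block, row-major; HC-LH and HC-RH use the same within-hemisphere
    ordering so homologous connections share a feature index.  TC excludes
    homotopic pairs.
    """
    iu, ju = np.triu_indices(p, k=1)
    if kind == "HC-LH":
        return np.column_stack([iu, ju])
    if kind == "HC-RH":
        return np.column_stack([iu + p, ju + p])
    if kind == "TC":
        i, j = np.meshgrid(np.arange(p), np.arange(p), indexing="ij")
        keep = i.ravel() != j.ravel()
        return np.column_stack([i.ravel()[keep], j.ravel()[keep] + p])
    if kind == "FC":
        return np.vstack(
            [feature_pairs(p, "HC-LH"), feature_pairs(p, "HC-RH"), feature_pairs(p, "TC")]
        )
    raise ValueError(f"unknown feature kind {kind!r}")


def extract_features(
    conn: ConnectivityMatrix | np.ndarray, atlas: ParcelAtlas, kind: str
) -> FeatureVectorSet:
    """Extract a connectome feature vector from a connectivity matrix."""
    values = conn.values if isinstance(conn, ConnectivityMatrix) else np.asarray(conn)
    if values.shape != (atlas.n_parcels, atlas.n_parcels):
        raise ValueError(
            f"matrix shape {values.shape} does not match atlas "
            f"({atlas.n_parcels} parcels)"
        )
    pairs = feature_pairs(atlas.parcels_per_hemi, kind)
    return FeatureVectorSet(kind=kind, vector=values[pairs[:, 0], pairs[:, 1]], index_map=pairs)


def features_to_matrix(
    vector: np.ndarray, index_map: np.ndarray, n_parcels: int, fill: float = 0.0
) -> np.ndarray:
    """Reassemble feature values into a symmetric ``n_parcels`` square matrix."""
    out = np.full((n_parcels, n_parcels), fill, dtype=float)
    out[index_map[:, 0], index_map[:, 1]] = vector
    out[index_map[:, 1], index_map[:, 0]] = vector
    np.fill_diagonal(out, 0.0)
    return out


def hemi_mask_to_matrix(mask: np.ndarray, p: int) -> np.ndarray:
    """Map a hemiconnectome feature mask onto a symmetric P x P matrix."""
    pairs = feature_pairs(p, "HC-LH")
    out = np.zeros((p, p), dtype=bool)
    out[pairs[:, 0], pairs[:, 1]] = mask
    return out | out.T


def symmetrize_networks(atlas: ParcelAtlas) -> tuple[ParcelAtlas, int]:
    """Give both members of every homologue pair the LH network label.

    Returns the updated atlas and the number of discordant homologue pairs.
    """
    p = atlas.parcels_per_hemi
    lh_labels = atlas.network_raw[:p]
    rh_labels = atlas.network_raw[p:]
    discordant = sum(a != b for a, b in zip(lh_labels, rh_labels))
    sym = tuple(lh_labels) * 2
    return replace(atlas, network_sym=sym), discordant


def merge_and_drop_networks(
    atlas: ParcelAtlas,
    merge_rules: Mapping[str, Iterable[str]] | None = None,
    drop_rules: Iterable[str] | None = None,
) -> ParcelAtlas:
    """Apply network merge/drop rules and record the kept network set.

    Merged source labels are replaced with the merged label; parcels of
    dropped networks are flagged ``excluded`` (they remain in every feature
    vector — exclusion applies only to enrichment grouping).  With the
    default Cole-Anticevic rules (merge the two visual networks, drop the
    three <=3-parcel networks) 8 networks are kept, giving 36 enrichment
    groups.
    """
    if atlas.network_sym is None:
        atlas, _ = symmetrize_networks(atlas)
    merge_rules = dict(merge_rules) if merge_rules is not None else dict(DEFAULT_MERGE_RULES)
    drop_rules = tuple(drop_rules) if drop_rules is not None else DEFAULT_DROP_RULES

    labels = list(atlas.network_sym)
    present = set(labels)
    rename: dict[str, str] = {}
    for target, sources in merge_rules.items():
        for src in sources:
            if src not in present:
                raise ValueError(f"merge rule references unknown network {src!r}")
            rename[src] = target
    for label in drop_rules:
        if label not in present and label not in rename.values():
            raise ValueError(f"drop rule references unknown network {label!r}")
    labels = [rename.get(lbl, lbl) for lbl in labels]
    dropped = set(drop_rules)
    excluded = tuple(lbl in dropped for lbl in labels)
    kept = tuple(sorted(set(labels) - dropped))
    return replace(
        atlas, network_sym=tuple(labels), kept_networks=kept, excluded=excluded
    )


def write_feature_matrix(
    path: str | Path,
    X: np.ndarray,
    index_map: np.ndarray,
    row_ids: Sequence[str],
) -> None:
    """Write a samples x features TSV plus a sidecar JSON index map."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(X), index=list(row_ids))
    df.to_csv(path, sep="\t", header=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"index_map": np.asarray(index_map).tolist()}, separators=(",", ":"))
    )
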