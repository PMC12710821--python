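"""Two-stage permutation enrichment of discriminating connections.

Stage 1 — connection-level significance.  An LDA is fit on the observed
hemisphere-labelled feature matrix and its per-feature LD1 scalings are
kept.  Null scalings come from refitting the LDA after shuffling the
hemisphere labels within each subject's pair of samples (preserving the
two-samples-per-subject structure).  Each feature's two-sided empirical
p-value is the rank-proportion statistic

    p = min(1, 2 * min(frac(null <= obs), frac(null >= obs)))

with exact zeros replaced by the permutation floor ``3 / reps``.
Connections with ``p < alpha`` (default .01) form the significance mask.

Stage 2 — network-pair enrichment.  Each hemiconnectome feature joins one
of ``k(k+1)/2`` groups (unordered pair of kept networks, or a single
within-network group); features touching dropped networks are outside the
grouping.  The observed significant-connection count per group is compared
with counts from uniformly shuffling the significant flags over grouped
upper-triangle positions (a shuffle that, mirrored back onto the matrix,
preserves its symmetry), giving a one-sided-greater empirical p per group,
floored at ``3 / reps``, followed by Benjamini-Hochberg FDR over the
groups.

A word of caution carried over from the method's framing: LDA scalings do
not straightforwardly measure "feature importance" — a connection with a
small between-hemisphere difference may receive a large scaling.  They are
reported as model scalings, nothing more.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from hemiconn.classify import fit_oriented_lda
from hemiconn.connectome import ParcelAtlas, feature_pairs

__all__ = [
    "EnrichmentResult",
    "empirical_p_two_sided",
    "p_floor",
    "connection_significance",
    "network_group_map",
    "group_enrichment",
    "fdr_correct",
    "sign_summary",
    "enrichment_analysis",
]


def p_floor(reps: int) -> float:
    """Smallest reportable simulated p-value: 3 / repetitions."""
    return 3.0 / reps


@dataclass
class EnrichmentResult:
    """Connection-level and network-group-level enrichment output."""

    observed_scalings: np.ndarray
    connection_p: np.ndarray
    mask: np.ndarray
    alpha: float
    reps: int
    group_names: tuple[str, ...]
    group_counts: np.ndarray
    group_p: np.ndarray
    group_p_fdr: np.ndarray
    n_lh_greater: int
    n_rh_greater: int

    def group_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "group": self.group_names,
                "count": self.group_counts,
                "p": self.group_p,
                "p_fdr": self.group_p_fdr,
            }
        )


def empirical_p_two_sided(
    observed: float | np.ndarray, null: np.ndarray, reps: int | None = None
) -> float | np.ndarray:
    """Two-sided rank-proportion p-value against an empirical null.

    ``null`` is either 1-D (shared null) or (reps, n_features) with one
    column per observed value.  Values below the simulation floor
    ``3 / reps`` are raised to it.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    n_reps = null.shape[0]
    if reps is not None and reps != n_reps:
        raise ValueError(f"reps={reps} does not match null size {n_reps}")
    if n_reps < 100:
        raise ValueError("need at least 100 null replicates")
    obs = np.asarray(observed, dtype=float)
    lower = (null <= obs).mean(axis=0)
    upper = (null >= obs).mean(axis=0)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    p = np.maximum(p, p_floor(n_reps))
    return float(p) if np.ndim(observed) == 0 else p


def _shuffle_within_subjects(
    y: np.ndarray, subject_ids: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Permute labels within each subject's rows (hemisphere-label shuffle)."""
    out = y.copy()
    for s in np.unique(subject_ids):
        rows = np.flatnonzero(subject_ids == s)
        out[rows] = out[rng.permutation(rows)]
    return out


def connection_significance(
    X: np.ndarray,
    y: Sequence[str],
    subject_ids: Sequence[str],
    reps: int = 10_000,
    alpha: float = 0.01,
    seed: int = 0,
    negative_class: str = "LH",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-connection empirical p-values of LDA scalings vs a shuffled null.

    Returns ``(observed_scalings, p_values, mask)`` where the scalings are
    oriented so the ``negative_class`` mean LD1 score is negative (positive
    scaling => connection loads toward the other class).
    """
    X = np.asarray(X)
    y = np.asarray(y)
    subject_ids = np.asarray(subject_ids)
    if p_floor(reps) >= alpha:
        warnings.warn(
            f"reps={reps} gives p-floor {p_floor(reps):.4g} >= alpha={alpha}; "
            "no connection can clear the threshold reliably",
            stacklevel=2,
        )
    lda, sign = fit_oriented_lda(X, y, negative_class=negative_class)
    observed = sign * lda.scalings_[:, 0]
    rng = np.random.default_rng(seed)
    null = np.empty((reps, X.shape[1]))
    for r in range(reps):
        y_perm = _shuffle_within_subjects(y, subject_ids, rng)
        lda_null, sign_null = fit_oriented_lda(X, y_perm, negative_class=negative_class)
        null[r] = sign_null * lda_null.scalings_[:, 0]
    p = empirical_p_two_sided(observed, null)
    return observed, p, p < alpha


def network_group_map(atlas: ParcelAtlas) -> tuple[np.ndarray, tuple[str, ...]]:
    """Map each hemiconnectome feature to a network-pair group.

    Returns ``(group_ids, group_names)``; ``group_ids[f]`` is the index of
    feature ``f``'s group in ``group_names``, or -1 when either parcel
    belongs to a dropped network.  Group names cover all ``k(k+1)/2``
    unordered pairs of kept networks (within-network groups included),
    even those containing no feature at small parcel counts.
    """
    if atlas.kept_networks is None:
        raise ValueError("atlas needs kept_networks; run merge_and_drop_networks first")
    kept = list(atlas.kept_networks)
    names: list[str] = []
    index: dict[tuple[str, str], int] = {}
    for i, a in enumerate(kept):
        for b in kept[i:]:
            index[(a, b)] = len(names)
            names.append(f"{a}-{b}" if a != b else f"within-{a}")
    labels = atlas.networks[: atlas.parcels_per_hemi]
    pairs = feature_pairs(atlas.parcels_per_hemi, "HC-LH")
    group_ids = np.full(len(pairs), -1, dtype=int)
    for f, (i, j) in enumerate(pairs):
        key = tuple(sorted((labels[i], labels[j])))
        group_ids[f] = index.get(key, -1)
    return group_ids, tuple(names)


def group_enrichment(
    mask: np.ndarray,
    group_ids: np.ndarray,
    n_groups: int,
    reps: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group significant-connection counts and one-sided empirical p.

    The null shuffles the observed number of significant flags uniformly
    over the grouped feature positions; since every hemiconnectome feature
    is a single upper-triangle position mirrored onto both matrix halves,
    the shuffle preserves matrix symmetry by construction.
    """
    mask = np.asarray(mask, dtype=bool)
    group_ids = np.asarray(group_ids)
    if mask.shape != group_ids.shape:
        raise ValueError("mask and group map must align")
    grouped = group_ids >= 0
    gid = group_ids[grouped]
    n_grouped = int(grouped.sum())
    observed = np.bincount(gid[mask[grouped]], minlength=n_groups)
    m = int(mask[grouped].sum())
    if m == 0:
        return observed, np.ones(n_groups)
    rng = np.random.default_rng(seed)
    null_counts = np.empty((reps, n_groups), dtype=int)
    for r in range(reps):
        pos = rng.choice(n_grouped, size=m, replace=False)
        null_counts[r] = np.bincount(gid[pos], minlength=n_groups)
    p = (null_counts >= observed).mean(axis=0)
    p = np.maximum(np.minimum(p, 1.0), p_floor(reps))
    return observed, p


def fdr_correct(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def sign_summary(
    observed_scalings: np.ndarray, mask: np.ndarray
) -> tuple[int, int]:
    """Partition significant connections by oriented scaling sign.

    With LD1 oriented so the LH class mean is negative, a negative scaling
    marks a connection loading toward LH (LH > RH) and a positive scaling
    toward RH (RH > LH).  Returns ``(n_lh_greater, n_rh_greater)``.
    """
    sig = np.asarray(observed_scalings)[np.asarray(mask, dtype=bool)]
    return int((sig < 0).sum()), int((sig > 0).sum())


def enrichment_analysis(
    X: np.ndarray,
    y: Sequence[str],
    subject_ids: Sequence[str],
    atlas: ParcelAtlas,
    reps: int = 10_000,
    alpha: float = 0.01,
    seed: int = 0,
) -> EnrichmentResult:
    """Full two-stage enrichment: connection significance, grouping, FDR."""
    ss = np.random.SeedSequence(seed)
    s_conn, s_group = (int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(2))
    observed, p_conn, mask = connection_significance(
        X, y, subject_ids, reps=reps, alpha=alpha, seed=s_conn
    )
    group_ids, names = network_group_map(atlas)
    counts, p_group = group_enrichment(
        mask, group_ids, n_groups=len(names), reps=reps, seed=s_group
    )
    p_fdr = fdr_correct(p_group)
    n_lh, n_rh = sign_summary(observed, mask)
    return EnrichmentResult(
        observed_scalings=observed,
        connection_p=p_conn,
        mask=mask,
        alpha=alpha,
        reps=reps,
        group_names=names,
        group_counts=counts,
        group_p=p_group,
        group_p_fdr=p_fdr,
        n_lh_greater=n_lh,
        n_rh_greater=n_rh,
    )
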