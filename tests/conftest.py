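"""Shared fixtures: reduced-scale synthetic cohorts and heavy simulation results.

Expensive simulations (the desk-scale cohorts, enrichment recovery, type-I
calibration, bootstrap coverage) are session-scoped so each is computed
once and asserted on from both the module suites and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from hemiconn import classify as clf
from hemiconn import enrichment as enr
from hemiconn import pipeline as pl
from hemiconn import synthetic as syn
from hemiconn.synthetic import CohortSpec, EhiModel

#: A 20-parcel, four-network parcellation used for reduced-scale tests.
SMALL_NETWORKS = (("DMN", 6), ("FPN", 5), ("LN", 4), ("SMN", 5))


def small_spec(**overrides) -> CohortSpec:
    defaults = dict(
        n_subjects=20,
        parcels_per_hemi=20,
        timepoints=300,
        networks=SMALL_NETWORKS,
        seed=1234,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


def cohort_datasets(cohort):
    matrices = pl.connectivity_matrices(cohort)
    handedness = dict(zip(cohort.metadata["subject_id"], cohort.metadata["handedness"]))
    return matrices, handedness


@pytest.fixture(scope="session")
def tiny_dextral_cohort():
    """20 dextral subjects, P=20, with the default planted asymmetry."""
    return syn.generate_cohort(small_spec(ehi_model=EhiModel(dextral_mass=1.0)))


@pytest.fixture(scope="session")
def desk_dextral_run():
    """The reduced-scale chirality experiment: n=200 dextral subjects,
    P=40, T=300, default planted asymmetry, 5-fold LDA."""
    spec = CohortSpec.desk_scale(ehi_model=EhiModel(dextral_mass=1.0), seed=20_240)
    cohort = syn.generate_cohort(spec)
    matrices, handedness = cohort_datasets(cohort)
    data = pl.chirality_dataset(matrices, cohort.atlas)
    run = clf.cross_validated_run(
        data["X"], data["y"], data["subjects"], handedness,
        model_kind="LDA", outcome="chirality", n_folds=5, seed=7,
    )
    return {"cohort": cohort, "data": data, "run": run}


@pytest.fixture(scope="session")
def desk_mixed_fourway_run():
    """Four-way (chirality x handedness) LDA on the default mixed cohort."""
    spec = CohortSpec.desk_scale(seed=20_241)
    cohort = syn.generate_cohort(spec)
    matrices, handedness = cohort_datasets(cohort)
    data = pl.fourway_dataset(matrices, cohort.atlas, handedness)
    run = clf.cross_validated_run(
        data["X"], data["y"], data["subjects"], handedness,
        model_kind="LDA", outcome="fourway", n_folds=5, seed=7,
    )
    hemi_t, hand_t = clf.decompose_fourway(run.y_true)
    hemi_p, hand_p = clf.decompose_fourway(run.y_pred)
    return {
        "run": run,
        "chirality_mcc": clf.mcc(clf.confusion(hemi_t, hemi_p)),
        "handedness_mcc": clf.mcc(clf.confusion(hand_t, hand_p)),
    }


@pytest.fixture(scope="session")
def enrichment_recovery():
    """Planted-asymmetry enrichment at reduced scale over 20 seeds.

    Each seed: 40 dextral subjects, P=40, T=300, default planted offsets,
    1,000 permutation reps for both stages.
    """
    planted = ("DMN-LN", "FPN-LN", "within-DMN")
    results = []
    for seed in range(20):
        spec = CohortSpec.desk_scale(
            n_subjects=40, ehi_model=EhiModel(dextral_mass=1.0), seed=3000 + seed
        )
        cohort = syn.generate_cohort(spec)
        matrices, _ = cohort_datasets(cohort)
        data = pl.chirality_dataset(matrices, cohort.atlas)
        res = enr.enrichment_analysis(
            data["X"], data["y"], data["subjects"], cohort.atlas,
            reps=1000, alpha=0.01, seed=seed,
        )
        fdr = dict(zip(res.group_names, res.group_p_fdr))
        counts = dict(zip(res.group_names, res.group_counts))
        results.append(
            {
                "planted_fdr": {g: fdr[g] for g in planted},
                "planted_counts": {g: counts[g] for g in planted},
                "other_counts": {g: c for g, c in counts.items() if g not in planted},
                "floor": enr.p_floor(res.reps),
                "min_connection_p": float(res.connection_p.min()),
                "min_group_p": float(res.group_p.min()),
                "mask": res.mask,
                "n_lh_greater": res.n_lh_greater,
                "n_rh_greater": res.n_rh_greater,
                "parcels_per_hemi": cohort.atlas.parcels_per_hemi,
            }
        )
    return results


@pytest.fixture(scope="session")
def null_calibration():
    """Group-level enrichment on 50 null cohorts (no planted asymmetry).

    Reduced scale per cohort: 24 subjects, P=20, 500 reps.  Alongside the
    empirical rejections, computes the exact attainable rejection level of
    the discrete permutation test from the closed-form hypergeometric
    shuffle null (the independent oracle for the uniform-position shuffle),
    including the Monte-Carlo smoothing of the 500-rep empirical p.
    """
    reps, alpha_mask, alpha_group, n_cohorts = 500, 0.01, 0.05, 50
    crit = int(np.floor(alpha_group * reps))  # p_emp < .05 iff tail count <= crit-1
    group_pvals = []
    connection_rates = []
    expected_rejections = []
    for seed in range(n_cohorts):
        spec = small_spec(n_subjects=24, asymmetry_map={}, seed=5000 + seed)
        cohort = syn.generate_cohort(spec)
        matrices, _ = cohort_datasets(cohort)
        data = pl.chirality_dataset(matrices, cohort.atlas)
        _, p_conn, mask = enr.connection_significance(
            data["X"], data["y"], data["subjects"],
            reps=reps, alpha=alpha_mask, seed=seed,
        )
        connection_rates.append(float((p_conn < alpha_mask).mean()))
        gid, names = enr.network_group_map(cohort.atlas)
        counts, p_group = enr.group_enrichment(
            mask, gid, n_groups=len(names), reps=reps, seed=900 + seed
        )
        group_pvals.extend(p_group.tolist())
        # exact attainable rejection probability per group, given this mask size
        grouped = gid >= 0
        n_grouped = int(grouped.sum())
        m = int(mask[grouped].sum())
        sizes = np.bincount(gid[grouped], minlength=len(names))
        for n_g in sizes:
            if m == 0 or n_g == 0:
                expected_rejections.append(0.0)
                continue
            xs = np.arange(0, min(m, n_g) + 1)
            pmf = stats.hypergeom.pmf(xs, n_grouped, n_g, m)
            tail = stats.hypergeom.sf(xs - 1, n_grouped, n_g, m)  # P(X >= x)
            # P(empirical tail count <= crit-1) given true tail prob
            p_reject = stats.binom.cdf(crit - 1, reps, tail)
            expected_rejections.append(float((pmf * p_reject).sum()))
    return {
        "group_pvals": np.asarray(group_pvals),
        "alpha_group": alpha_group,
        "expected_rate": float(np.mean(expected_rejections)),
        "connection_rates": np.asarray(connection_rates),
        "alpha_mask": alpha_mask,
    }


@pytest.fixture(scope="session")
def bootstrap_coverage():
    """Coverage of the bootstrap MCC CI over 200 simulated experiments.

    Balanced binary truth (n=120), predictions flip with probability .1 per
    sample, so the long-run MCC is .8.
    """
    rng = np.random.default_rng(0)
    true_mcc, n, covered = 0.8, 120, 0
    for s in range(200):
        y = np.repeat([0, 1], n // 2)
        flip = rng.random(n) < 0.1
        y_pred = np.where(flip, 1 - y, y)
        _, lo, hi = clf.bootstrap_mcc_ci(y, y_pred, reps=500, seed=s)
        covered += lo <= true_mcc <= hi
    return covered / 200
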