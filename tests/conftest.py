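"""Shared fixtures: embedding parameters and small synthetic cohorts."""

import numpy as np
import pytest

from slnet.sl import SlParams
from slnet.synthetic import CohortConfig, default_block_map


@pytest.fixture(scope="session")
def default_params() -> SlParams:
    """The study's embedding parameters: lag 1, dim 6, Theiler 6, Pref 0.01."""
    return SlParams(lag=1, dim=6, theiler=6, pref=0.01)


@pytest.fixture(scope="session")
def short_params() -> SlParams:
    """Parameters usable on short series (for brute-force oracle checks)."""
    return SlParams(lag=1, dim=3, theiler=2, pref=0.05)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


def tiny_cohort_config(seed: int = 0, n_per_group: int = 6,
                       n_regions: int = 12, n_timepoints: int = 80,
                       **overrides) -> CohortConfig:
    """A minimal cohort that exercises all six lobe blocks."""
    kwargs = dict(n_control=n_per_group, n_patient=n_per_group,
                  n_regions=n_regions, n_timepoints=n_timepoints, seed=seed,
                  block_map=default_block_map(n_regions))
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def ad_lambda_replicates():
    """Corrected path length lambda by group over 20 seeded replicates of
    the AD-like cohort at the package's scaled study conditions.

    Conditions (documented in the methods note): 60 regions, 16 + 16
    subjects, 200 timepoints, lambda averaged over fixed mean degrees
    K in {5, 6} with 16 rewired surrogates each; both the full region
    set and the cerebellum-excluded subset are evaluated (SL is
    bivariate, so the reduced set is the submatrix).

    Returns a list of dicts with per-replicate group means:
    ``{"full": (lam_control, lam_patient), "nocereb": (...)}``.
    """
    import numpy as _np

    from slnet.graphs import corrected_metrics, graph_from_degree
    from slnet.sl import sl_matrix
    from slnet.synthetic import simulate_cohort

    k_levels = (5, 6)
    out = []
    for rep in range(20):
        cfg = tiny_cohort_config(seed=rep, n_per_group=16, n_regions=60,
                                 n_timepoints=200)
        keep = _np.array([b != "cerebellar" for b in cfg.block_map])
        subjects = simulate_cohort(cfg)
        lam = {"full": {"control": [], "patient": []},
               "nocereb": {"control": [], "patient": []}}
        for i, s in enumerate(subjects):
            mat = sl_matrix(s)
            sub_vals = mat.values[_np.ix_(keep, keep)]
            from slnet.sl import SyncMatrix
            sub = SyncMatrix(values=sub_vals,
                             region_labels=tuple(
                                 _np.asarray(mat.region_labels)[keep]))
            for tag, m in (("full", mat), ("nocereb", sub)):
                vals = [corrected_metrics(graph_from_degree(m, k),
                                          n_surrogates=16,
                                          seed=[rep, i, k, tag == "full"]).lam
                        for k in k_levels]
                lam[tag][s.group].append(_np.mean(vals))
        out.append({tag: (float(_np.mean(lam[tag]["control"])),
                          float(_np.mean(lam[tag]["patient"])))
                    for tag in ("full", "nocereb")})
    return out
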