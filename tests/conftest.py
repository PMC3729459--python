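import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import crossarray as ca

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_catalog():
    return ca.generate_catalog(50, 200, seed=1)


@pytest.fixture(scope="session")
def small_probes(small_catalog):
    affy = ca.generate_probes(small_catalog, "AFFY25", probes_per_probeset=11, seed=1)
    ilmn = ca.generate_probes(small_catalog, "ILMN50", seed=1)
    return affy, ilmn


@pytest.fixture(scope="session")
def study_bundle():
    """300-transcript three-study bundle with defaults mirroring the source
    study designs (36 NP; 12 PE + 11 NP; 37 PE + 58 NP)."""
    catalog = ca.generate_catalog(300, 250, seed=3)
    cfg = ca.SimulationConfig(n_transcripts=300, seed=3)
    matrices, metadata, truth = ca.generate_studies(catalog, cfg)
    return catalog, cfg, matrices, metadata, truth


@pytest.fixture(scope="session")
def pooled_bundle(study_bundle):
    """Double-INT-normalized, pooled matrix over the trivial pair table."""
    from crossarray import normalization as nz

    catalog, cfg, matrices, metadata, truth = study_bundle
    pairs = ca.ProbePairTable(ca.default_pair_table(catalog))
    normed = [nz.double_int(m) for m in matrices]
    pooled = nz.align_to_pairs(normed, pairs, ["AFFY25", "AFFY25", "ILMN50"])
    return pooled, pairs, metadata, truth


def simulate_variances(d0, s0_sq, df, n, seed):
    """Residual variances from the hierarchical model s^2 ~ s0^2 F(df, d0)."""
    rng = np.random.default_rng(seed)
    sigma2 = s0_sq * d0 / rng.chisquare(d0, size=n)
    return sigma2 * rng.chisquare(df, size=n) / df


def bh_brute_force(p, m):
    """Step-up enumeration oracle: adj_(i) = min_{j >= i} min(1, m p_(j)/j)."""
    p = np.asarray(p)
    order = np.argsort(p, kind="stable")
    n = len(p)
    adj = np.empty(n)
    for pos in range(n):
        adj[order[pos]] = min(
            min(1.0, m * p[order[j]] / (j + 1)) for j in range(pos, n)
        )
    return adj


def pi0_slsqp_oracle(p, grid_size=25):
    """Discretized convex-regression oracle for pi0: maximize the mixture
    likelihood with a generic constrained optimizer instead of EM."""
    from scipy import optimize

    from crossarray.diffexpr import _tent_density_matrix

    theta = np.linspace(1.0 / grid_size, 1.0, grid_size)
    F = _tent_density_matrix(np.asarray(p, float), theta)
    k = F.shape[1]

    def nll(w):
        return -np.log(np.maximum(F @ w, 1e-300)).mean()

    res = optimize.minimize(
        nll, np.full(k, 1.0 / k), method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    return float(res.x[0])


def brute_force_matches(probe_seq, catalog, max_mismatch=1):
    """Sliding-window Hamming scan over every transcript and both strands;
    independent oracle for the seeded matcher."""
    from crossarray.probe_mapping import reverse_complement

    L = len(probe_seq)
    out = {}
    for entry in catalog.entries:
        seq = entry.sequence
        for start in range(len(seq) - L + 1):
            window = seq[start : start + L]
            for strand, s in (("sense", probe_seq), ("revcomp", reverse_complement(probe_seq))):
                d = sum(a != b for a, b in zip(window, s))
                if d <= max_mismatch:
                    key = (entry.transcript_id, start)
                    if key not in out or d < out[key][0]:
                        out[key] = (d, strand)
    return {k: v[0] for k, v in out.items()}
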