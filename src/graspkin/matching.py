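"""Outlier-tolerant, order-penalised matching of grasp sequences.

A grasp is an M x D matrix of per-frame posture embeddings.  Matching two
grasps means assigning every frame i of the first to a frame pi(i) of the
second or to the outlier label 0, minimising

    sum_i cost(i, pi(i)) + lambda * sum_i 1(pi(i) > pi(i+1))

subject to |pi(i) - i| <= B for matched frames, where cost(i, j) is the
Euclidean embedding distance for j >= 1 and a fixed outlier penalty tau
for j = 0.  The order-violation indicator is evaluated literally on the
pi values including 0.

Because the objective couples only consecutive assignments, the exact
optimum is available three ways: an integer linear program (HiGHS), a
chain dynamic program, and exhaustive enumeration for tiny instances.
All three agree exactly; the DP is the fast path for large simulations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .codebook import spectral_medoid_clustering


@dataclass
class MatchingProblem:
    """Two sequences plus matching parameters (lambda, band B, outlier tau)."""

    seq_a: np.ndarray  # (M, D)
    seq_b: np.ndarray  # (M', D)
    lam: float = 1.0
    band: int = 10
    tau: float = 1.0

    def __post_init__(self) -> None:
        self.seq_a = np.atleast_2d(np.asarray(self.seq_a, dtype=float))
        self.seq_b = np.atleast_2d(np.asarray(self.seq_b, dtype=float))
        if self.seq_a.shape[1] != self.seq_b.shape[1]:
            raise ValueError("sequences must share the embedding dimension")
        if self.lam < 0 or self.band < 0 or self.tau <= 0:
            raise ValueError("need lambda >= 0, B >= 0, tau > 0")

    def cost_matrix(self) -> np.ndarray:
        """(M, M'+1) costs; column 0 is the outlier penalty tau."""
        diff = self.seq_a[:, None, :] - self.seq_b[None, :, :]
        c = np.linalg.norm(diff, axis=2)
        return np.hstack([np.full((len(self.seq_a), 1), self.tau), c])

    def allowed(self, i: int) -> list[int]:
        """Assignment options for frame i (1-based target indices, 0 = outlier)."""
        mp = len(self.seq_b)
        lo, hi = max(1, i + 1 - self.band), min(mp, i + 1 + self.band)
        return [0] + list(range(lo, hi + 1))


@dataclass
class MatchingResult:
    pi: np.ndarray  # length M, values in {0, 1, ..., M'}
    objective: float
    distance: float  # sum of embedding distances over matched frames
    status: str
    n_outliers: int = field(init=False)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=int)
        self.n_outliers = int((self.pi == 0).sum())


def _evaluate(problem: MatchingProblem, pi: np.ndarray, cost: np.ndarray
              ) -> tuple[float, float]:
    match_cost = float(sum(cost[i, pi[i]] for i in range(len(pi))))
    violations = int(np.sum(pi[:-1] > pi[1:]))
    dist = float(sum(cost[i, pi[i]] for i in range(len(pi)) if pi[i] >= 1))
    return match_cost + problem.lam * violations, dist


def _solve_dp(problem: MatchingProblem, cost: np.ndarray) -> np.ndarray:
    """Chain DP over the per-frame option sets (exact; ties -> smallest pi).

    Options are sorted ascending, so the minimum over non-violating
    predecessors (pi(i-1) <= j) is a prefix minimum and the violating
    ones (pi(i-1) > j, +lambda) a suffix minimum.
    """
    m = len(problem.seq_a)
    opts = [np.asarray(problem.allowed(i)) for i in range(m)]
    val = cost[0, opts[0]].astype(float)
    back: list[np.ndarray] = []
    for i in range(1, m):
        prev, cur = opts[i - 1], opts[i]
        np_prev = len(prev)
        # prefix minima (ties -> smallest predecessor index)
        pmin = np.minimum.accumulate(val)
        parg = np.zeros(np_prev, dtype=int)
        for k in range(1, np_prev):
            parg[k] = parg[k - 1] if pmin[k - 1] <= val[k] else k
        # suffix minima (ties -> smallest predecessor index)
        smin = np.empty(np_prev)
        sarg = np.empty(np_prev, dtype=int)
        smin[-1], sarg[-1] = val[-1], np_prev - 1
        for k in range(np_prev - 2, -1, -1):
            if val[k] <= smin[k + 1]:
                smin[k], sarg[k] = val[k], k
            else:
                smin[k], sarg[k] = smin[k + 1], sarg[k + 1]
        split = np.searchsorted(prev, cur, side="right")
        newval = np.empty(len(cur))
        bk = np.empty(len(cur), dtype=int)
        for t, j in enumerate(cur):
            s = split[t]
            cand_keep = pmin[s - 1] if s > 0 else np.inf
            cand_viol = (smin[s] + problem.lam) if s < np_prev else np.inf
            if cand_keep <= cand_viol:
                newval[t], bk[t] = cand_keep, parg[s - 1]
            else:
                newval[t], bk[t] = cand_viol, sarg[s]
        val = newval + cost[i, cur]
        back.append(bk)
    jbest = int(np.argmin(val))  # first minimum = smallest option value
    idx = [jbest]
    for bk in reversed(back):
        idx.append(int(bk[idx[-1]]))
    idx = idx[::-1]
    return np.array([opts[i][k] for i, k in enumerate(idx)], dtype=int)


def _solve_ilp(problem: MatchingProblem, cost: np.ndarray) -> tuple[np.ndarray, str]:
    m = len(problem.seq_a)
    options = [problem.allowed(i) for i in range(m)]
    # variable layout: assignment z_{i,j} for j in options[i], then
    # violation indicators v_i for i = 0..m-2
    offsets = np.cumsum([0] + [len(o) for o in options])
    nz = int(offsets[-1])
    nv = m - 1
    c = np.concatenate(
        [np.array([cost[i, j] for j in options[i]]) for i in range(m)]
        + [np.full(nv, problem.lam)]
    )
    rows, cols, vals, lo, hi = [], [], [], [], []
    r = 0
    for i in range(m):  # sum_j z_{i,j} = 1
        for k in range(len(options[i])):
            rows.append(r)
            cols.append(offsets[i] + k)
            vals.append(1.0)
        lo.append(1.0)
        hi.append(1.0)
        r += 1
    for i in range(m - 1):  # v_i >= z_{i,j} + z_{i+1,j'} - 1 for j > j'
        for k, j in enumerate(options[i]):
            for k2, j2 in enumerate(options[i + 1]):
                if j > j2:
                    rows += [r, r, r]
                    cols += [offsets[i] + k, offsets[i + 1] + k2, nz + i]
                    vals += [1.0, 1.0, -1.0]
                    lo.append(-np.inf)
                    hi.append(1.0)
                    r += 1
    a = sp.csc_array((vals, (rows, cols)), shape=(r, nz + nv))
    res = milp(
        c,
        constraints=LinearConstraint(a, lo, hi),
        bounds=Bounds(0, 1),
        integrality=np.ones(nz + nv),
    )
    if res.status != 0:
        raise RuntimeError(f"ILP solver failed: {res.message}")
    z = res.x[:nz]
    pi = np.empty(m, dtype=int)
    for i in range(m):
        k = int(np.argmax(z[offsets[i] : offsets[i + 1]]))
        pi[i] = options[i][k]
    return pi, "optimal"


def _solve_enumeration(problem: MatchingProblem, cost: np.ndarray) -> np.ndarray:
    m = len(problem.seq_a)
    if m > 8 or problem.band > 3:
        raise ValueError("enumeration oracle limited to M <= 8 and B <= 3")
    best_pi, best_obj = None, np.inf
    for pi in itertools.product(*(problem.allowed(i) for i in range(m))):
        pi = np.array(pi)
        obj, _ = _evaluate(problem, pi, cost)
        if obj < best_obj - 1e-15:
            best_obj, best_pi = obj, pi
    return best_pi


def match_sequences(
    problem: MatchingProblem, method: str = "dp"
) -> MatchingResult:
    """Exact optimum of the matching objective.

    ``method`` is one of ``"exact_ilp"`` (integer linear program, HiGHS),
    ``"dp"`` (chain dynamic program; same optimum, fast path) or
    ``"oracle"`` (exhaustive enumeration, tiny instances only).
    """
    cost = problem.cost_matrix()
    if method == "exact_ilp":
        pi, status = _solve_ilp(problem, cost)
    elif method == "dp":
        pi, status = _solve_dp(problem, cost), "optimal"
    elif method == "oracle":
        pi, status = _solve_enumeration(problem, cost), "optimal"
    else:
        raise ValueError(f"unknown method {method!r}")
    obj, dist = _evaluate(problem, pi, cost)
    for i, j in enumerate(pi):
        assert j == 0 or abs(j - (i + 1)) <= problem.band
    return MatchingResult(pi=pi, objective=obj, distance=dist, status=status)


def median_frame_cost(
    grasps: list[np.ndarray], rng: np.random.Generator | None = None,
    max_pairs: int = 50,
) -> float:
    """Median per-frame embedding distance over sampled grasp pairs.

    Used to set the default outlier penalty tau and order weight lambda on
    a dataset's own scale.
    """
    rng = rng or np.random.default_rng(0)
    n = len(grasps)
    if n < 2:
        raise ValueError("need at least two grasps")
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if len(pairs) > max_pairs:
        pairs = [pairs[k] for k in rng.choice(len(pairs), max_pairs, replace=False)]
    vals = []
    for i, j in pairs:
        diff = grasps[i][:, None, :] - grasps[j][None, :, :]
        vals.append(np.linalg.norm(diff, axis=2).ravel())
    return float(np.median(np.concatenate(vals)))


@dataclass
class MatchingParams:
    """Dataset-level matching parameters; lam/tau default to the median frame cost."""

    lam: float | None = None
    band: int = 10
    tau: float | None = None
    method: str = "dp"

    def resolve(self, grasps: list[np.ndarray]) -> "MatchingParams":
        if self.lam is not None and self.tau is not None:
            return self
        med = median_frame_cost(grasps)
        return MatchingParams(
            lam=self.lam if self.lam is not None else med,
            band=self.band,
            tau=self.tau if self.tau is not None else med,
            method=self.method,
        )

    def problem(self, a: np.ndarray, b: np.ndarray) -> MatchingProblem:
        if self.lam is None or self.tau is None:
            raise ValueError("parameters not resolved; call resolve() first")
        return MatchingProblem(a, b, lam=self.lam, band=self.band, tau=self.tau)


def sequence_distance(
    seq_a: np.ndarray,
    seq_b: np.ndarray,
    params: MatchingParams,
    symmetric: bool = False,
) -> float:
    """Matched-frame embedding distance d(S, S') under the optimal alignment.

    ``symmetric`` returns d_sym = (d(a,b) + d(b,a)) / 2, used wherever a
    metric-like quantity is required.
    """
    d_ab = match_sequences(params.problem(seq_a, seq_b), method=params.method).distance
    if not symmetric:
        return d_ab
    d_ba = match_sequences(params.problem(seq_b, seq_a), method=params.method).distance
    return 0.5 * (d_ab + d_ba)


def pairwise_sequence_distances(
    grasps: list[np.ndarray], params: MatchingParams
) -> np.ndarray:
    n = len(grasps)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sequence_distance(
                grasps[i], grasps[j], params, symmetric=True
            )
    return d


@dataclass
class SequenceCodebook:
    """Canonical grasping sequences (cluster medoids of the training grasps)."""

    prototypes: list[np.ndarray]
    member_indices: np.ndarray
    assignments: np.ndarray
    params: MatchingParams

    def __len__(self) -> int:
        return len(self.prototypes)


def build_sequence_dictionary(
    grasps: list[np.ndarray],
    Q: int,
    params: MatchingParams | None = None,
    seed: int = 0,
) -> SequenceCodebook:
    """Cluster grasps under d_sym (normalized cuts, as for the posture codebook).

    Distances are turned into similarities by negation plus a shift to
    non-negative; prototypes are the cluster medoids.
    """
    if Q > len(grasps):
        raise ValueError(f"Q={Q} exceeds number of grasps {len(grasps)}")
    params = (params or MatchingParams()).resolve(grasps)
    d = pairwise_sequence_distances(grasps, params)
    sim = -d
    labels, medoids = spectral_medoid_clustering(sim, Q, seed=seed)
    return SequenceCodebook(
        prototypes=[grasps[m] for m in medoids],
        member_indices=medoids,
        assignments=labels,
        params=params,
    )


def embed_sequence_level(
    seq: np.ndarray, dictionary: SequenceCodebook
) -> np.ndarray:
    """F' = vector of d_sym distances from one grasp to every prototype."""
    if not len(dictionary):
        raise ValueError("empty sequence dictionary")
    return np.array(
        [
            sequence_distance(seq, proto, dictionary.params, symmetric=True)
            for proto in dictionary.prototypes
        ]
    )
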