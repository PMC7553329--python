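"""Independent oracles used by the tests.

``brute_force_min`` minimizes the blockwise objective by iteratively refined
dense grid search over the box [-1, 1]^d, keeping several top cells per round
to guard against the nonconvexity of the truncated-LASSO penalty. It shares
no code with the coordinate-descent solver.
"""

import numpy as np


def penalty_values(B: np.ndarray, penalty) -> np.ndarray:
    """J(beta) for each row of B, matching the solver's lambda convention."""
    a = np.abs(B)
    lam = penalty.lam
    if penalty.kind == "lasso":
        return 2.0 * lam * a.sum(axis=1)
    if penalty.kind == "elastic_net":
        return 2.0 * penalty.alpha * lam * a.sum(axis=1) + (1.0 - penalty.alpha) * lam * (
            B**2
        ).sum(axis=1)
    return 2.0 * lam * np.minimum(a, penalty.tau).sum(axis=1)


def objective_values(B: np.ndarray, r: np.ndarray, R: np.ndarray, penalty) -> np.ndarray:
    s = penalty.s
    quad = (1.0 - s) * np.einsum("ij,jk,ik->i", B, R, B) + s * (B**2).sum(axis=1)
    return quad - 2.0 * B @ r + penalty_values(B, penalty)


def brute_force_min(
    r: np.ndarray,
    R: np.ndarray,
    penalty,
    rounds: int = 9,
    pts: int = 13,
    keep: int = 6,
) -> float:
    """Global minimum of the blockwise objective over [-1, 1]^d by zoomed grid."""
    d = len(r)
    boxes = [(np.full(d, -1.0), np.full(d, 1.0))]
    best = np.inf
    for _ in range(rounds):
        cands = []
        for lo, hi in boxes:
            axes = [np.linspace(lo[k], hi[k], pts) for k in range(d)]
            B = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, d)
            f = objective_values(B, r, R, penalty)
            order = np.argsort(f)[:keep]
            width = (hi - lo) / (pts - 1)
            for i in order:
                cands.append((float(f[i]), B[i], width))
        cands.sort(key=lambda t: t[0])
        best = min(best, cands[0][0])
        boxes = [
            (np.maximum(c - w, -1.0), np.minimum(c + w, 1.0)) for _, c, w in cands[:keep]
        ]
    return best


def random_block_problem(rng: np.random.Generator, d: int):
    """A random (r, R, ridge-bounded) fixture whose minimizer stays in the box."""
    A = rng.standard_normal((d + 4, d))
    R = np.atleast_2d(np.corrcoef(A, rowvar=False))
    r = rng.uniform(-0.6, 0.6, size=d)
    s = rng.uniform(0.2, 1.0)
    ridge = np.linalg.solve((1.0 - s) * R + s * np.eye(d), r)
    if np.abs(ridge).max() > 0.9:
        r = r * 0.9 / np.abs(ridge).max()
    return r, R, s
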