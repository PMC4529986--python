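"""Independent brute-force oracles used only by the test suite."""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def _quat_to_mats(quats: np.ndarray) -> np.ndarray:
    return Rotation.from_quat(quats).as_matrix()


def oracle_least_squares(x: np.ndarray, y: np.ndarray, n_quat: int = 20000,
                         seed: int = 0) -> float:
    """Brute-force d_LS: global search over sampled unit quaternions followed
    by derivative-free local refinement of the rotation.

    For a fixed rotation the optimal translation is closed-form (centroid
    alignment), so the objective depends on the rotation alone.  This never
    touches the SVD solution path it is used to check.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)

    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_quat, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    mats = _quat_to_mats(quats)
    rotated = np.einsum("qij,nj->qni", mats, yc)
    ss = np.sum((xc[None] - rotated) ** 2, axis=(1, 2))
    best = int(np.argmin(ss))

    def objective(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        d = xc - yc @ r.T
        return float(np.sum(d * d))

    rv0 = Rotation.from_matrix(mats[best]).as_rotvec()
    res = minimize(objective, rv0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
    return float(np.sqrt(max(min(res.fun, ss[best]), 0.0)))


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic (midranks for ties)."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = labels.sum()
    n0 = labels.size - n1
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
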