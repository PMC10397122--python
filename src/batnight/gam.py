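"""Penalized Bernoulli additive model (logit link) with regression-spline smooths.

The nightly presence probability is modelled as

    y ~ Bernoulli(p),    logit(p) = Intercept + sum_j f_j(x_j) + alpha

where each ``f_j`` is a penalized regression spline (low-rank thin-plate,
cyclic cubic, or a tensor product of thin-plate marginals), a centered
linear term, or a dummy-coded factor, and ``alpha`` is a post-fit
calibration constant (zero during fitting; see :mod:`batnight.calibration`).

Fitting maximizes the Bernoulli log-likelihood minus the quadratic
roughness penalty ``1/2 sum_j lambda_j b' S_j b`` by penalized iteratively
reweighted least squares (PIRLS) with step-halving.  Per-term smoothing
parameters are chosen by a deterministic coordinate-wise grid descent on
an AIC-type criterion (deviance + 2 * effective degrees of freedom).

Every smooth is made identifiable by absorbing a sum-to-zero constraint
over the training rows into the basis, so smooth terms average out to
zero and the intercept carries the overall level.  The coefficient
covariance is the Bayesian one, the inverse of the penalized information,
which yields the usual GAM credible/confidence bands.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import null_space
from scipy.special import expit, logit

__all__ = [
    "SmoothSpec", "DEFAULT_MODEL_SPEC", "Design", "GamModel",
    "assemble_design", "fit_pirls", "select_lambda", "fit_gam",
    "predict_probability", "effect_curve", "factor_contrasts",
    "dunn_smyth_residuals", "term_wald_table",
]

MAX_TP_KNOTS = 200          # thin-plate knot budget before subsampling
ETA_GUARD = 30.0            # |linear predictor| beyond which separation is suspected
RIDGE_FALLBACK = 1e-6


class GamError(ValueError):
    pass


@dataclass(frozen=True)
class SmoothSpec:
    """Specification of one model term.

    ``kind`` is one of ``thin_plate``, ``cyclic_cubic``, ``tensor``,
    ``linear``, ``factor``.  ``k`` is the basis dimension (a pair of
    marginal dimensions for tensors); ``boundary`` the cyclic wrap points.
    """

    covariates: tuple[str, ...]
    kind: str
    k: int | tuple[int, int] | None = None
    boundary: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind in ("thin_plate", "cyclic_cubic") and (self.k is None or self.k < 3):
            raise GamError(f"{self.kind} smooth needs k >= 3, got {self.k}")
        if self.kind == "cyclic_cubic" and self.k < 4:
            raise GamError(f"cyclic_cubic smooth needs k >= 4, got {self.k}")
        if self.kind == "tensor" and len(self.covariates) < 2:
            raise GamError("tensor smooth needs >= 2 marginal covariates")

    @property
    def label(self) -> str:
        prefix = {"thin_plate": "tp", "cyclic_cubic": "cc", "tensor": "te",
                  "linear": "lin", "factor": "factor"}[self.kind]
        return f"{prefix}({','.join(self.covariates)})"


#: The model used for the nightly presence analysis: a spatial tensor
#: smooth, thin-plate smooths for seasonal timing and the weather shapes,
#: a cyclic smooth for lunar phase, linear pressure and rain, year factor.
DEFAULT_MODEL_SPEC: tuple[SmoothSpec, ...] = (
    SmoothSpec(("lon", "lat"), "tensor", (5, 5)),
    SmoothSpec(("night_in_year",), "thin_plate", 10),
    SmoothSpec(("pressure_change",), "thin_plate", 6),
    SmoothSpec(("tailwind",), "thin_plate", 6),
    SmoothSpec(("crosswind",), "thin_plate", 6),
    SmoothSpec(("cloud",), "thin_plate", 6),
    SmoothSpec(("lunar_phase",), "cyclic_cubic", 8, (0.0, 360.0)),
    SmoothSpec(("pressure",), "linear"),
    SmoothSpec(("rain",), "linear"),
    SmoothSpec(("year",), "factor"),
)


# ---------------------------------------------------------------------------
# Basis construction
# ---------------------------------------------------------------------------

def _tp_eta(r: np.ndarray) -> np.ndarray:
    """1-D thin-plate radial basis function, |r|^3 / 12."""
    return np.abs(r) ** 3 / 12.0


def _tp_raw(x: np.ndarray, k: int):
    """Eigen-truncated thin-plate machinery on one covariate.

    Returns ``(knots, M, S_raw)``: raw columns for data ``z`` are
    ``[eta(|z - knots|) @ M, 1, z]`` (k columns, the last two spanning the
    unpenalized null space {1, x}); ``S_raw`` (k x k) has rank k - 2.
    """
    xu = np.unique(x[np.isfinite(x)])
    if len(xu) < k:
        raise GamError(f"thin-plate basis of rank {k} needs >= {k} distinct values, "
                       f"have {len(xu)}")
    if len(xu) > MAX_TP_KNOTS:
        q = np.linspace(0, 1, MAX_TP_KNOTS)
        knots = np.unique(np.quantile(xu, q))
    else:
        knots = xu
    m = len(knots)
    E = _tp_eta(knots[:, None] - knots[None, :])
    w, V = np.linalg.eigh(E)
    order = np.argsort(-np.abs(w))[: k - 2 + 2]  # keep k leading components
    Uk = V[:, order[:k]]
    Dk = w[order[:k]]
    T = np.column_stack([np.ones(m), knots])
    C = T.T @ Uk                                  # 2 x k
    Zc = null_space(C)                            # k x (k-2)
    M = Uk @ Zc                                   # m x (k-2)
    P = Zc.T @ (Dk[:, None] * Zc)                 # (k-2) x (k-2), PSD
    S_raw = np.zeros((k, k))
    S_raw[: k - 2, : k - 2] = P
    return knots, M, S_raw


def _tp_columns(z: np.ndarray, knots: np.ndarray, M: np.ndarray) -> np.ndarray:
    K = _tp_eta(z[:, None] - knots[None, :])
    return np.column_stack([K @ M, np.ones_like(z), z])


def _cyclic_machinery(k: int, boundary: tuple[float, float]):
    """Cyclic cubic regression spline: knots, second-derivative map F, penalty.

    Parameters are the function values at the k knots (the k+1-th knot
    wraps onto the first).  ``F = B^{-1} D`` maps knot values to knot
    second derivatives; the roughness penalty is ``D' B^{-1} D``, the
    integrated squared second derivative.
    """
    b0, b1 = boundary
    knots = np.linspace(b0, b1, k + 1)
    h = np.diff(knots)
    B = np.zeros((k, k))
    D = np.zeros((k, k))
    for j in range(k):
        jm = (j - 1) % k
        jp = (j + 1) % k
        B[j, jm] += h[jm] / 6.0
        B[j, j] += (h[jm] + h[j]) / 3.0
        B[j, jp] += h[j] / 6.0
        D[j, jm] += 1.0 / h[jm]
        D[j, j] += -1.0 / h[jm] - 1.0 / h[j]
        D[j, jp] += 1.0 / h[j]
    Binv = np.linalg.inv(B)
    F = Binv @ D
    S_raw = D.T @ Binv @ D
    S_raw = 0.5 * (S_raw + S_raw.T)
    return knots, F, S_raw


def _cyclic_columns(z: np.ndarray, knots: np.ndarray, F: np.ndarray) -> np.ndarray:
    k = F.shape[0]
    b0, b1 = knots[0], knots[-1]
    if np.any((z < b0) | (z > b1)):
        raise GamError(f"cyclic covariate outside boundary [{b0}, {b1}]")
    j = np.clip(np.searchsorted(knots, z, side="right") - 1, 0, k - 1)
    t0 = knots[j]
    t1 = knots[j + 1]
    h = t1 - t0
    xm = z - t0
    xp = t1 - z
    jp = (j + 1) % k
    X = np.zeros((len(z), k))
    rows = np.arange(len(z))
    X[rows, j] += xp / h
    X[rows, jp] += xm / h
    cm = -xm * xp / 6.0 * (1.0 + xp / h)
    cp = -xm * xp / 6.0 * (1.0 + xm / h)
    X += cm[:, None] * F[j, :]
    X += cp[:, None] * F[jp, :]
    return X


def _row_kron(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.einsum("ij,ik->ijk", A, B).reshape(A.shape[0], -1)


def _normalize(S: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(S)
    return S / nrm if nrm > 0 else S


# --- fitted basis blocks ----------------------------------------------------

@dataclass
class TermBlock:
    """One fitted model term: columns, penalties, and how to rebuild them.

    ``penalties`` are symmetric PSD matrices in the block's own coordinate
    system (empty for linear/factor terms).  ``payload`` carries the arrays
    needed to evaluate the basis on new data and to serialize the model.
    """

    spec: SmoothSpec
    ncols: int
    penalties: list[np.ndarray]
    payload: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return self.spec.label

    # -- evaluation on (new) data -----------------------------------------
    def columns(self, table: pd.DataFrame) -> np.ndarray:
        kind = self.spec.kind
        p = self.payload
        if kind == "thin_plate":
            z = table[self.spec.covariates[0]].to_numpy(float)
            raw = _tp_columns(z, np.asarray(p["knots"]), np.asarray(p["M"]))
            return raw @ np.asarray(p["Z"])
        if kind == "cyclic_cubic":
            z = table[self.spec.covariates[0]].to_numpy(float)
            raw = _cyclic_columns(z, np.asarray(p["knots"]), np.asarray(p["F"]))
            return raw @ np.asarray(p["Z"])
        if kind == "tensor":
            z1 = table[self.spec.covariates[0]].to_numpy(float)
            z2 = table[self.spec.covariates[1]].to_numpy(float)
            X1 = _tp_columns(z1, np.asarray(p["knots1"]), np.asarray(p["M1"]))
            X2 = _tp_columns(z2, np.asarray(p["knots2"]), np.asarray(p["M2"]))
            return _row_kron(X1, X2) @ np.asarray(p["Z"])
        if kind == "linear":
            z = table[self.spec.covariates[0]].to_numpy(float)
            return (z - p["mean"])[:, None]
        if kind == "factor":
            vals = table[self.spec.covariates[0]].astype(str).to_numpy()
            levels = list(p["levels"])
            unseen = sorted(set(vals) - set(levels))
            if unseen:
                raise GamError(f"unseen factor level(s) {unseen} for {self.label}")
            return np.column_stack([(vals == lv).astype(float) for lv in levels[1:]]) \
                if len(levels) > 1 else np.zeros((len(vals), 0))
        raise GamError(f"unknown term kind {kind!r}")

    def training_range(self):
        return self.payload.get("range")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in self.payload.items()}
        return {"covariates": list(self.spec.covariates), "kind": self.spec.kind,
                "k": self.spec.k, "boundary": self.spec.boundary,
                "ncols": self.ncols, "payload": payload,
                "penalties": [S.tolist() for S in self.penalties]}

    @classmethod
    def from_dict(cls, d: dict) -> "TermBlock":
        k = d["k"]
        spec = SmoothSpec(tuple(d["covariates"]), d["kind"],
                          tuple(k) if isinstance(k, list) else k,
                          tuple(d["boundary"]) if d["boundary"] else None)
        payload = {key: (np.asarray(v) if isinstance(v, list) else v)
                   for key, v in d["payload"].items()}
        return cls(spec, d["ncols"], [np.asarray(S) for S in d["penalties"]], payload)


def build_term(spec: SmoothSpec, table: pd.DataFrame) -> TermBlock:
    """Construct one term block from training data (constraint absorbed)."""
    kind = spec.kind
    if kind == "thin_plate":
        z = table[spec.covariates[0]].to_numpy(float)
        knots, M, S_raw = _tp_raw(z, int(spec.k))
        raw = _tp_columns(z, knots, M)
        Z = null_space(raw.sum(axis=0, keepdims=True))
        S = _normalize(Z.T @ S_raw @ Z)
        payload = {"knots": knots, "M": M, "Z": Z,
                   "range": (float(z.min()), float(z.max()))}
        return TermBlock(spec, Z.shape[1], [S], payload)
    if kind == "cyclic_cubic":
        z = table[spec.covariates[0]].to_numpy(float)
        boundary = spec.boundary or (float(z.min()), float(z.max()))
        knots, F, S_raw = _cyclic_machinery(int(spec.k), boundary)
        raw = _cyclic_columns(z, knots, F)
        Z = null_space(raw.sum(axis=0, keepdims=True))
        S = _normalize(Z.T @ S_raw @ Z)
        payload = {"knots": knots, "F": F, "Z": Z, "range": boundary}
        return TermBlock(spec, Z.shape[1], [S], payload)
    if kind == "tensor":
        k1, k2 = spec.k
        z1 = table[spec.covariates[0]].to_numpy(float)
        z2 = table[spec.covariates[1]].to_numpy(float)
        if not (np.isfinite(z1).all() and np.isfinite(z2).all()):
            raise GamError("non-finite coordinates in tensor smooth")
        knots1, M1, S1 = _tp_raw(z1, int(k1))
        knots2, M2, S2 = _tp_raw(z2, int(k2))
        X1 = _tp_columns(z1, knots1, M1)
        X2 = _tp_columns(z2, knots2, M2)
        raw = _row_kron(X1, X2)
        Z = null_space(raw.sum(axis=0, keepdims=True))
        SA = _normalize(Z.T @ np.kron(S1, np.eye(int(k2))) @ Z)
        SB = _normalize(Z.T @ np.kron(np.eye(int(k1)), S2) @ Z)
        payload = {"knots1": knots1, "M1": M1, "knots2": knots2, "M2": M2, "Z": Z,
                   "range": ((float(z1.min()), float(z1.max())),
                             (float(z2.min()), float(z2.max())))}
        return TermBlock(spec, Z.shape[1], [SA, SB], payload)
    if kind == "linear":
        z = table[spec.covariates[0]].to_numpy(float)
        payload = {"mean": float(z.mean()), "range": (float(z.min()), float(z.max()))}
        return TermBlock(spec, 1, [], payload)
    if kind == "factor":
        levels = sorted(table[spec.covariates[0]].astype(str).unique())
        return TermBlock(spec, max(len(levels) - 1, 0), [], {"levels": levels})
    raise GamError(f"unknown term kind {kind!r}")


# ---------------------------------------------------------------------------
# Design assembly
# ---------------------------------------------------------------------------

@dataclass
class Design:
    """Full model matrix (intercept first) plus per-term blocks and penalties."""

    blocks: list[TermBlock]
    X: np.ndarray
    y: np.ndarray
    slices: dict[str, slice]
    n_dropped: int

    @property
    def n_penalties(self) -> int:
        return sum(len(b.penalties) for b in self.blocks)

    def penalty_embeddings(self) -> list[np.ndarray]:
        """Each penalty expanded to full coefficient dimension."""
        p = self.X.shape[1]
        out = []
        for b in self.blocks:
            sl = self.slices[b.label]
            for S in b.penalties:
                full = np.zeros((p, p))
                full[sl, sl] = S
                out.append(full)
        return out

    def build_rows(self, table: pd.DataFrame) -> np.ndarray:
        """Model-matrix rows for new data (intercept included)."""
        parts = [np.ones((len(table), 1))]
        parts += [b.columns(table) for b in self.blocks]
        return np.hstack(parts)


def assemble_design(table: pd.DataFrame,
                    spec: tuple[SmoothSpec, ...] = DEFAULT_MODEL_SPEC,
                    response: str = "y") -> Design:
    """Build the full penalized design from the night table.

    Rows with a missing value in the response or any required covariate
    are dropped (complete-case) with the count recorded on the result.
    """
    needed = sorted({c for s in spec for c in s.covariates} | {response})
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise GamError(f"night table lacks column(s) {missing_cols}")
    complete = table.dropna(subset=needed).reset_index(drop=True)
    n_dropped = len(table) - len(complete)
    if len(complete) == 0:
        raise GamError("no complete rows left after dropping missing covariates")
    if n_dropped:
        import logging
        logging.getLogger("batnight").info(
            "assemble_design: dropped %d incomplete rows", n_dropped)

    blocks = [build_term(s, complete) for s in spec]
    parts = [np.ones((len(complete), 1))]
    slices = {}
    start = 1
    for b in blocks:
        cols = b.columns(complete)
        parts.append(cols)
        slices[b.label] = slice(start, start + b.ncols)
        start += b.ncols
    X = np.hstack(parts)
    y = complete[response].to_numpy(float)
    return Design(blocks, X, y, slices, n_dropped)


# ---------------------------------------------------------------------------
# Penalized IRLS
# ---------------------------------------------------------------------------

def _bernoulli_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


@dataclass
class GamModel:
    """A fitted penalized Bernoulli additive model.

    Holds the fitted coefficient vector (intercept first), per-penalty
    smoothing parameters, the Bayesian coefficient covariance, the basis
    blocks needed to rebuild model-matrix rows, and the post-fit
    calibration constant ``alpha`` (0 until set by the calibration step).
    """

    blocks: list[TermBlock]
    slices: dict[str, slice]
    beta: np.ndarray
    cov: np.ndarray
    lambdas: np.ndarray
    alpha: float = 0.0
    deviance: float = float("nan")
    edf: float = float("nan")
    n_obs: int = 0
    n_iter: int = 0
    converged: bool = True

    @property
    def required_columns(self) -> list[str]:
        """Covariates a prediction row must carry (non-missing)."""
        return sorted({c for b in self.blocks for c in b.spec.covariates})

    def complete_cases(self, table: pd.DataFrame) -> pd.DataFrame:
        """The rows of ``table`` with every model covariate present."""
        return table.dropna(subset=[c for c in self.required_columns
                                    if c in table.columns]).reset_index(drop=True)

    def design_rows(self, table: pd.DataFrame) -> np.ndarray:
        parts = [np.ones((len(table), 1))]
        parts += [b.columns(table) for b in self.blocks]
        return np.hstack(parts)

    def linear_predictor(self, table: pd.DataFrame, use_alpha: bool = False) -> np.ndarray:
        eta = self.design_rows(table) @ self.beta
        return eta + (self.alpha if use_alpha else 0.0)

    # thin wrappers over the module-level functions
    def predict_probability(self, table, use_alpha: bool = False):
        return predict_probability(self, table, use_alpha=use_alpha)

    def effect_curve(self, term, grid, level: float = 0.95):
        return effect_curve(self, term, grid, level=level)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "batnight-gam/1",
            "terms": [b.to_dict() for b in self.blocks],
            "slices": {k: [v.start, v.stop] for k, v in self.slices.items()},
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "lambdas": self.lambdas.tolist(),
            "alpha": self.alpha,
            "deviance": self.deviance,
            "edf": self.edf,
            "n_obs": self.n_obs,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "GamModel":
        blocks = [TermBlock.from_dict(t) for t in d["terms"]]
        slices = {k: slice(v[0], v[1]) for k, v in d["slices"].items()}
        return cls(blocks, slices, np.asarray(d["beta"]), np.asarray(d["cov"]),
                   np.asarray(d["lambdas"]), float(d["alpha"]),
                   float(d["deviance"]), float(d["edf"]), int(d["n_obs"]))

    @classmethod
    def from_json(cls, path) -> "GamModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_pirls(design: Design, lambdas, max_iter: int = 200,
              tol: float = 1e-8) -> GamModel:
    """Fit the penalized Bernoulli GAM at fixed smoothing parameters.

    Iteratively reweighted least squares on the penalized deviance with
    step-halving; convergence when the relative change of the penalized
    deviance drops below ``tol``.  The coefficient covariance returned is
    the penalized-information inverse.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.shape != (design.n_penalties,):
        raise GamError(f"need {design.n_penalties} smoothing parameters, "
                       f"got {lambdas.shape}")
    if np.any(lambdas < 0):
        raise GamError("smoothing parameters must be positive")
    X, y = design.X, design.y
    n, p = X.shape
    S = np.zeros((p, p))
    for lam, Sj in zip(lambdas, design.penalty_embeddings()):
        S += lam * Sj

    beta = np.zeros(p)
    ybar = float(np.clip(y.mean(), 1.0 / (n + 1), 1 - 1.0 / (n + 1)))
    beta[0] = logit(ybar)
    eta = X @ beta
    mu = expit(eta)
    pen_dev = _bernoulli_deviance(y, mu) + float(beta @ S @ beta)
    ridge_warned = False
    ridge = 0.0

    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        A = XtW @ X + S + ridge * np.eye(p)
        b = XtW @ z
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            ridge = max(ridge, RIDGE_FALLBACK)
            beta_new = np.linalg.solve(A + ridge * np.eye(p), b)

        # step-halving so the penalized deviance never increases
        step = beta_new - beta
        t = 1.0
        for _ in range(50):
            cand = beta + t * step
            eta_c = X @ cand
            dev_c = _bernoulli_deviance(y, expit(eta_c)) + float(cand @ S @ cand)
            if dev_c <= pen_dev + 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        eta = X @ beta
        mu = expit(eta)
        new_pen_dev = _bernoulli_deviance(y, mu) + float(beta @ S @ beta)

        if np.max(np.abs(eta)) > ETA_GUARD and ridge == 0.0:
            if not ridge_warned:
                warnings.warn("possible complete separation (|eta| large); "
                              "adding a small ridge for stability", RuntimeWarning)
                ridge_warned = True
            ridge = RIDGE_FALLBACK

        rel = abs(pen_dev - new_pen_dev) / (abs(new_pen_dev) + 1e-10)
        pen_dev = new_pen_dev
        if rel < tol:
            converged = True
            break
    if not converged:
        raise GamError(f"PIRLS did not converge in {max_iter} iterations "
                       f"(last penalized deviance {pen_dev:.6g})")

    w = np.clip(mu * (1 - mu), 1e-10, None)
    XtWX = (X.T * w) @ X
    A = XtWX + S + ridge * np.eye(p)
    cov = np.linalg.inv(A)
    edf = float(np.trace(cov @ XtWX))
    return GamModel(blocks=design.blocks, slices=design.slices, beta=beta, cov=cov,
                    lambdas=lambdas, alpha=0.0,
                    deviance=_bernoulli_deviance(y, mu), edf=edf,
                    n_obs=n, n_iter=n_iter, converged=True)


DEFAULT_LAMBDA_GRID = tuple(np.logspace(-2.0, 8.0, 21))

#: EDF inflation in the smoothness criterion.  Plain AIC (gamma = 1) is
#: known to undersmooth occasionally; 1.4 is the widely used remedy.
DEFAULT_EDF_GAMMA = 1.4


def select_lambda(design: Design, grid=DEFAULT_LAMBDA_GRID,
                  n_passes: int = 3, gamma: float = DEFAULT_EDF_GAMMA) -> np.ndarray:
    """Choose per-penalty smoothing parameters by coordinate grid descent.

    Minimizes ``deviance + 2 * gamma * edf`` (an AIC-type unbiased-risk
    criterion with the customary EDF inflation), sweeping each smoothing
    parameter over the grid in turn, holding the others fixed.
    Deterministic given the grid and the data.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size == 0:
        raise GamError("empty smoothing-parameter grid")
    m = design.n_penalties
    if m == 0:
        return np.zeros(0)
    start = grid[np.argmin(np.abs(np.log10(grid)))]  # grid value nearest 1
    lam = np.full(m, start)

    def criterion(lams):
        try:
            model = fit_pirls(design, lams)
        except GamError:
            return np.inf, None
        return model.deviance + 2.0 * gamma * model.edf, model

    best_crit, _ = criterion(lam)
    if not np.isfinite(best_crit):
        # try the grid extremes before giving up
        for g in (grid[-1], grid[0]):
            lam[:] = g
            best_crit, _ = criterion(lam)
            if np.isfinite(best_crit):
                break
    for _ in range(n_passes):
        changed = False
        for j in range(m):
            for g in grid:
                if g == lam[j]:
                    continue
                trial = lam.copy()
                trial[j] = g
                crit, _ = criterion(trial)
                if crit < best_crit - 1e-9:
                    best_crit = crit
                    lam = trial
                    changed = True
        if not changed:
            break
    if not np.isfinite(best_crit):
        raise GamError("smoothing-parameter criterion non-finite over the whole grid")
    return lam


def fit_gam(table: pd.DataFrame, spec=DEFAULT_MODEL_SPEC,
            lambda_grid=DEFAULT_LAMBDA_GRID, response: str = "y") -> GamModel:
    """Convenience: assemble design, select smoothing parameters, fit."""
    design = assemble_design(table, spec, response=response)
    lam = select_lambda(design, lambda_grid)
    return fit_pirls(design, lam)


# ---------------------------------------------------------------------------
# Prediction, effects, diagnostics
# ---------------------------------------------------------------------------

def predict_probability(model: GamModel, table: pd.DataFrame,
                        use_alpha: bool = False) -> np.ndarray:
    """Predicted presence probabilities, optionally with the alpha shift."""
    return expit(model.linear_predictor(table, use_alpha=use_alpha))


def effect_curve(model: GamModel, term: str, grid, level: float = 0.95) -> pd.DataFrame:
    """Partial-effect curve of one term on the probability scale.

    The term of interest varies along ``grid`` while every other term
    contributes zero: smooths are sum-to-zero centered so they average
    out, linear terms sit at their training means, and the factor sits at
    its reference level.  Bands are Wald intervals on the linear predictor
    mapped through the inverse logit.

    ``grid`` is a 1-D array for univariate terms or a DataFrame with the
    term's covariates (e.g. a lon/lat grid for the spatial surface).
    """
    block = _find_block(model, term)
    if isinstance(grid, pd.DataFrame):
        gtab = grid.reset_index(drop=True)
    else:
        grid = np.asarray(grid, dtype=float)
        gtab = pd.DataFrame({block.spec.covariates[0]: grid})
    _warn_extrapolation(block, gtab)

    p = len(model.beta)
    R = np.zeros((len(gtab), p))
    R[:, 0] = 1.0
    R[:, model.slices[block.label]] = block.columns(gtab)
    eta = R @ model.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", R, model.cov, R), 0.0))
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    out = gtab.copy()
    out["eta"] = eta
    out["probability"] = expit(eta)
    out["lower"] = expit(eta - zcrit * se)
    out["upper"] = expit(eta + zcrit * se)
    return out


def _find_block(model: GamModel, term: str) -> TermBlock:
    for b in model.blocks:
        if b.label == term or b.spec.covariates == (term,) or term in b.spec.covariates:
            return b
    raise GamError(f"term {term!r} not in model "
                   f"(have {[b.label for b in model.blocks]})")


def _warn_extrapolation(block: TermBlock, gtab: pd.DataFrame) -> None:
    rng = block.training_range()
    if rng is None:
        return
    ranges = rng if isinstance(rng[0], (tuple, list)) else (rng,)
    for cov, (lo, hi) in zip(block.spec.covariates, ranges):
        z = gtab[cov].to_numpy(float)
        if np.any((z < lo) | (z > hi)):
            warnings.warn(f"effect grid for {cov!r} extends beyond the training "
                          f"range [{lo:.4g}, {hi:.4g}]; extrapolating", RuntimeWarning)


def factor_contrasts(model: GamModel, factor: str = "year",
                     level: float = 0.95, n_mc: int = 100_000,
                     seed: int = 0) -> pd.DataFrame:
    """All pairwise factor-level differences with simultaneous CIs.

    Differences are on the linear-predictor (log-odds) scale.  The
    simultaneous critical value is the ``level`` quantile of the maximum
    absolute standardized contrast under the fitted multivariate-normal
    coefficient distribution, estimated by seeded Monte Carlo — the same
    family-wise correction a Tukey-style comparison provides.  With two
    levels it reduces to the unadjusted Wald interval.
    """
    block = _find_block(model, factor)
    if block.spec.kind != "factor":
        raise GamError(f"{factor!r} is not a factor term")
    levels = list(block.payload["levels"])
    if len(levels) < 2:
        raise GamError("factor contrasts need >= 2 levels")
    sl = model.slices[block.label]
    # coefficients including the reference level (0, by dummy coding)
    coefs = np.concatenate([[0.0], model.beta[sl]])
    V = np.zeros((len(levels), len(levels)))
    V[1:, 1:] = model.cov[sl, sl]

    pairs = [(i, j) for i in range(len(levels)) for j in range(i + 1, len(levels))]
    Cmat = np.zeros((len(pairs), len(levels)))
    for r, (i, j) in enumerate(pairs):
        Cmat[r, i] = 1.0
        Cmat[r, j] = -1.0
    est = Cmat @ coefs
    cov_c = Cmat @ V @ Cmat.T
    se = np.sqrt(np.maximum(np.diag(cov_c), 1e-300))

    if len(pairs) == 1:
        crit = stats.norm.ppf(0.5 + level / 2.0)
    else:
        corr = cov_c / np.outer(se, se)
        corr = 0.5 * (corr + corr.T)
        rng = np.random.default_rng(seed)
        evals, evecs = np.linalg.eigh(corr)
        Lhalf = evecs * np.sqrt(np.clip(evals, 0, None))
        zs = rng.standard_normal((n_mc, len(pairs))) @ Lhalf.T
        crit = float(np.quantile(np.max(np.abs(zs), axis=1), level))

    out = pd.DataFrame({
        "level_1": [levels[i] for i, _ in pairs],
        "level_2": [levels[j] for _, j in pairs],
        "estimate": est,
        "se": se,
        "lower": est - crit * se,
        "upper": est + crit * se,
    })
    out["significant"] = (out["lower"] > 0) | (out["upper"] < 0)
    return out


def dunn_smyth_residuals(model: GamModel, table: pd.DataFrame,
                         rng_seed: int = 0, response: str = "y") -> np.ndarray:
    """Randomized quantile residuals for the Bernoulli fit.

    For each observation a uniform draw is taken on the probability
    interval the outcome occupies under the fitted distribution —
    ``(0, 1-p)`` for y=0 and ``(1-p, 1)`` for y=1 — and mapped through the
    standard-normal quantile function.  Standard normal when the model is
    correctly specified; reproducible given the seed.
    """
    y = table[response].to_numpy(float)
    p = predict_probability(model, table)
    rng = np.random.default_rng(rng_seed)
    u0 = rng.uniform(size=len(y))
    lo = np.where(y > 0.5, 1.0 - p, 0.0)
    hi = np.where(y > 0.5, 1.0, 1.0 - p)
    u = np.clip(lo + u0 * (hi - lo), 1e-12, 1 - 1e-12)
    return stats.norm.ppf(u)


def term_wald_table(model: GamModel) -> pd.DataFrame:
    """Approximate Wald chi-square statistics per term.

    For each penalized or parametric term, ``b' V_b^{-1} b`` on the term's
    coefficients with the Bayesian covariance, referred to a chi-square
    with the term's column count.  These are approximate (the penalty
    biases the null distribution) and labelled as such in reports.
    """
    rows = []
    for b in model.blocks:
        sl = model.slices[b.label]
        bb = model.beta[sl]
        if bb.size == 0:
            continue
        Vb = model.cov[sl, sl]
        stat = float(bb @ np.linalg.solve(Vb, bb))
        df = bb.size
        rows.append({"term": b.label, "wald_chi2": stat, "df": df,
                     "p_value_approx": float(stats.chi2.sf(stat, df))})
    return pd.DataFrame(rows)
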