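"""Online sparse dictionary learning with elastic-net coding.

The sample x bucket matrix X (rows unit-normalized) is modeled column-wise:
each bucket profile x in R^m is a sparse non-negative combination of p
dictionary atoms ("eigengenomes", per-sample abundance profiles),

    min_{D in C} (1/n) sum_i  1/2 ||x_i - D a_i||^2
                              + lambda1 ||a_i||_1 + 1/2 lambda2 ||a_i||^2,

with the dictionary constrained to the convex set

    C = { D : ||d_j||_2^2 + gamma1 ||d_j||_1 + gamma2 FL(d_j) <= 1  for all j },

where FL is the fused-LASSO total variation sum_i |d[i+1] - d[i]| along the
sample axis. Learning alternates mini-batch elastic-net coding (coordinate
descent, optionally with positivity) with block coordinate descent on D
driven by accumulated sufficient statistics, the standard online scheme
for large dictionaries. Buckets are clustered by the argmax of their code.

Columns are internally scaled to unit l2 norm before coding (zero columns
are skipped and left uncoded): the coding penalties are calibrated for
unit-scale data vectors, and the argmax cluster rule is unaffected by a
positive per-column rescaling applied consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .abundance import AbundanceMatrix

__all__ = [
    "Dictionary",
    "CodeMatrix",
    "BucketAssignment",
    "learn_dictionary",
    "code_columns",
    "objective_value",
    "assign_buckets",
    "factorize_matrix",
    "coding_kkt_residual",
]

_FEAS_TOL = 1e-6


@dataclass
class Dictionary:
    """Learned dictionary D (m samples x p components) and its hyperparameters."""

    D: np.ndarray
    l1: float
    l2: float
    gamma1: float = 0.0
    gamma2: float = 0.0
    nonneg_dict: bool = True
    nonneg_code: bool = True
    seed: int = 0
    objective_history: list[float] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.D.shape[1]


@dataclass
class CodeMatrix:
    """Coefficients A (p x n) for the coded columns, with their bucket ids."""

    coeffs: np.ndarray
    bucket_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.coeffs.shape[1] != self.bucket_ids.size:
            raise ValueError("coeffs/bucket_ids size mismatch")


@dataclass
class BucketAssignment:
    """bucket -> cluster map; -1 means unassigned.

    Cluster ids are contiguous 0..n_clusters-1 after empty components have
    been dropped; ``component_map`` records original component -> cluster id.
    """

    bucket_ids: np.ndarray
    labels: np.ndarray
    n_clusters: int
    component_map: dict[int, int]

    def lookup(self, n_buckets: int) -> np.ndarray:
        """Dense bucket -> cluster array of length n_buckets (-1 unassigned)."""
        table = np.full(n_buckets, -1, dtype=np.int64)
        table[self.bucket_ids] = self.labels
        return table

    def save_tsv(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            fh.write("bucket\tcluster\n")
            for b, c in zip(self.bucket_ids, self.labels):
                fh.write(f"{b}\t{c}\n")

    @classmethod
    def load_tsv(cls, path: Path | str) -> "BucketAssignment":
        buckets, labels = [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("bucket"):
                raise ValueError("missing bucket/cluster header")
            for line in fh:
                b, c = line.split("\t")
                buckets.append(int(b))
                labels.append(int(c))
        labels_arr = np.asarray(labels, dtype=np.int64)
        used = np.unique(labels_arr[labels_arr >= 0])
        return cls(
            bucket_ids=np.asarray(buckets, dtype=np.int64),
            labels=labels_arr,
            n_clusters=used.size,
            component_map={int(c): int(c) for c in used},
        )


def _dict_constraint(d: np.ndarray, gamma1: float, gamma2: float) -> float:
    val = float(d @ d)
    if gamma1:
        val += gamma1 * float(np.abs(d).sum())
    if gamma2:
        val += gamma2 * float(np.abs(np.diff(d)).sum())
    return val


def _project_atom(
    d: np.ndarray, gamma1: float, gamma2: float, nonneg: bool
) -> np.ndarray:
    """Project an atom onto C (clip, then shrink radially; bisection when
    the gamma terms are active, exact l2-ball projection otherwise)."""
    if nonneg:
        d = np.maximum(d, 0.0)
    if gamma1 == 0.0 and gamma2 == 0.0:
        norm = np.linalg.norm(d)
        return d / norm if norm > 1.0 else d
    if _dict_constraint(d, gamma1, gamma2) <= 1.0:
        return d
    lo, hi = 0.0, 1.0
    for _ in range(60):  # constraint is monotone in the scale
        mid = 0.5 * (lo + hi)
        if _dict_constraint(mid * d, gamma1, gamma2) > 1.0:
            hi = mid
        else:
            lo = mid
    return lo * d


def _coordinate_descent(
    G: np.ndarray,
    DtX: np.ndarray,
    l1: float,
    l2: float,
    nonneg: bool,
    tol: float = 1e-10,
    max_sweeps: int = 2000,
) -> np.ndarray:
    """Elastic-net coding by cyclic coordinate descent, vectorized over
    columns: solves min_a 1/2||x - Da||^2 + l1||a||_1 + 1/2 l2||a||^2 for
    every column of DtX simultaneously (one coordinate at a time)."""
    p, n = DtX.shape
    A = np.zeros((p, n))
    diag = np.diag(G).copy()
    denom = diag + l2
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            if denom[j] <= 0.0:
                continue
            # residual correlation with atom j, excluding its own contribution
            r = DtX[j] - G[j] @ A + diag[j] * A[j]
            if nonneg:
                new = np.maximum(r - l1, 0.0) / denom[j]
            else:
                new = np.sign(r) * np.maximum(np.abs(r) - l1, 0.0) / denom[j]
            delta = np.abs(new - A[j]).max() if n else 0.0
            if delta > max_delta:
                max_delta = delta
            A[j] = new
        if max_delta <= tol:
            break
    return A


def code_columns(
    X,
    D: np.ndarray | Dictionary,
    l1: Optional[float] = None,
    l2: Optional[float] = None,
    nonneg: Optional[bool] = None,
    normalize_columns: bool = True,
) -> np.ndarray:
    """Code the columns of X against dictionary D; returns A (p x n).

    X may be a dense array or scipy sparse matrix of shape (m, n). Zero
    columns get a zero code. Parameters default to those stored on a
    :class:`Dictionary`.
    """
    if isinstance(D, Dictionary):
        l1 = D.l1 if l1 is None else l1
        l2 = D.l2 if l2 is None else l2
        nonneg = D.nonneg_code if nonneg is None else nonneg
        D = D.D
    if l1 is None or l2 is None:
        raise ValueError("l1 and l2 required when D is a plain array")
    if nonneg is None:
        nonneg = True
    if not np.isfinite(D).all():
        raise ValueError("dictionary contains non-finite entries")
    Xd = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=np.float64)
    if Xd.ndim != 2 or Xd.shape[0] != D.shape[0]:
        raise ValueError(f"X shape {Xd.shape} incompatible with D {D.shape}")
    if not np.isfinite(Xd).all():
        raise ValueError("input contains non-finite entries")
    if normalize_columns:
        norms = np.linalg.norm(Xd, axis=0)
        nz = norms > 0
        Xd = np.where(nz, Xd / np.where(nz, norms, 1.0), 0.0)
    G = D.T @ D
    A = _coordinate_descent(G, D.T @ Xd, l1, l2, nonneg)
    return A


def coding_kkt_residual(
    X, D: np.ndarray, A: np.ndarray, l1: float, l2: float, nonneg: bool
) -> float:
    """Maximum violation of the elastic-net optimality conditions at A."""
    Xd = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=np.float64)
    grad = D.T @ (D @ A - Xd) + l2 * A  # gradient of the smooth part
    if nonneg:
        active = np.abs(grad + l1) * (A > 0)
        inactive = np.maximum(-(grad + l1), 0.0) * (A <= 0)
        return float(np.maximum(active, inactive).max(initial=0.0))
    active = np.abs(grad + l1 * np.sign(A)) * (A != 0)
    inactive = np.maximum(np.abs(grad) - l1, 0.0) * (A == 0)
    return float(np.maximum(active, inactive).max(initial=0.0))


def objective_value(X, D: np.ndarray, A: np.ndarray, l1: float, l2: float) -> float:
    """(1/n) sum_i [ 1/2||x_i - D a_i||^2 + l1||a_i||_1 + 1/2 l2||a_i||^2 ]."""
    Xd = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=np.float64)
    n = Xd.shape[1]
    if n == 0:
        return 0.0
    resid = Xd - D @ A
    val = 0.5 * np.sum(resid * resid) + l1 * np.abs(A).sum() + 0.5 * l2 * np.sum(A * A)
    return float(val / n)


def _init_dictionary(
    Xc: np.ndarray, p: int, rng: np.random.Generator,
    gamma1: float, gamma2: float, nonneg: bool,
) -> np.ndarray:
    """Warm start: p distinct nonzero data columns, projected onto C."""
    norms = np.linalg.norm(Xc, axis=0)
    candidates = np.flatnonzero(norms > 0)
    if candidates.size < p:
        raise ValueError(f"need at least p={p} nonzero columns, have {candidates.size}")
    chosen = rng.choice(candidates, size=p, replace=False)
    D = Xc[:, chosen] / norms[chosen]
    return np.column_stack(
        [_project_atom(D[:, j], gamma1, gamma2, nonneg) for j in range(p)]
    )


def _update_dictionary(
    D: np.ndarray,
    A_stat: np.ndarray,
    B_stat: np.ndarray,
    gamma1: float,
    gamma2: float,
    nonneg: bool,
    n_passes: int = 2,
    eps: float = 1e-12,
) -> np.ndarray:
    """Block coordinate descent on the atoms given sufficient statistics
    A_stat = sum a a^T and B_stat = sum x a^T."""
    p = D.shape[1]
    for _ in range(n_passes):
        for j in range(p):
            if A_stat[j, j] <= eps:
                continue  # unused atom this round; left untouched
            u = D[:, j] + (B_stat[:, j] - D @ A_stat[:, j]) / A_stat[j, j]
            D[:, j] = _project_atom(u, gamma1, gamma2, nonneg)
    return D


def learn_dictionary(
    X,
    p: int,
    l1: float = 0.1,
    l2: float = 0.01,
    gamma1: float = 0.0,
    gamma2: float = 0.0,
    batch_size: int = 512,
    epochs: int = 5,
    seed: int = 0,
    nonneg_dict: bool = True,
    nonneg_code: bool = True,
    normalize_columns: bool = True,
    track_objective: Optional[bool] = None,
) -> Dictionary:
    """Learn the dictionary from the columns of X (dense or sparse, m x n).

    Mini-batch mode accumulates sufficient statistics across batches; when a
    single batch covers all columns (``batch_size >= n``), each epoch is one
    exact alternating-minimization step (code all columns, then block
    coordinate descent on D), which makes the tracked objective
    non-increasing epoch to epoch. ``objective_history`` records the
    objective on the training columns after every epoch. Deterministic for
    fixed inputs and seed.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if l1 < 0 or l2 < 0:
        raise ValueError("penalties must be non-negative")
    Xc = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=np.float64)
    if not np.isfinite(Xc).all():
        raise ValueError("input contains non-finite entries")
    m, n = Xc.shape
    if p > n:
        raise ValueError(f"p={p} exceeds number of columns n={n}")
    if normalize_columns:
        norms = np.linalg.norm(Xc, axis=0)
        nz = norms > 0
        Xc = np.where(nz, Xc / np.where(nz, norms, 1.0), 0.0)
    rng = np.random.default_rng(seed)
    D = _init_dictionary(Xc, p, rng, gamma1, gamma2, nonneg_dict)

    full_batch = batch_size >= n
    if track_objective is None:
        # per-epoch objective needs a full coding pass; free in full-batch
        # mode, costly in mini-batch mode, so off there by default
        track_objective = full_batch
    A_stat = np.zeros((p, p))
    B_stat = np.zeros((m, p))
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        if full_batch:
            A = _coordinate_descent(D.T @ D, D.T @ Xc, l1, l2, nonneg_code)
            A_stat = A @ A.T
            B_stat = Xc @ A.T
            D = _update_dictionary(D, A_stat, B_stat, gamma1, gamma2, nonneg_dict,
                                   n_passes=5)
            history.append(objective_value(Xc, D, A, l1, l2))
            continue
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            Xb = Xc[:, idx]
            Ab = _coordinate_descent(D.T @ D, D.T @ Xb, l1, l2, nonneg_code)
            A_stat += Ab @ Ab.T
            B_stat += Xb @ Ab.T
            D = _update_dictionary(D, A_stat, B_stat, gamma1, gamma2, nonneg_dict)
        if track_objective:
            A = _coordinate_descent(D.T @ D, D.T @ Xc, l1, l2, nonneg_code)
            history.append(objective_value(Xc, D, A, l1, l2))

    # feasibility guard: every atom must lie in C
    for j in range(p):
        if _dict_constraint(D[:, j], gamma1, gamma2) > 1.0 + _FEAS_TOL:
            raise AssertionError("dictionary atom left the constraint set")
    return Dictionary(
        D=D, l1=l1, l2=l2, gamma1=gamma1, gamma2=gamma2,
        nonneg_dict=nonneg_dict, nonneg_code=nonneg_code, seed=seed,
        objective_history=history,
    )


def assign_buckets(code: CodeMatrix | np.ndarray, bucket_ids=None) -> BucketAssignment:
    """Cluster buckets by the argmax component of their code.

    All-zero columns are unassigned; ties go to the smallest component
    index; empty components are dropped with a stable re-indexing map.
    """
    if isinstance(code, CodeMatrix):
        A, bucket_ids = code.coeffs, code.bucket_ids
    else:
        A = np.asarray(code)
        if bucket_ids is None:
            bucket_ids = np.arange(A.shape[1])
    raw = np.argmax(A, axis=0)  # first maximum -> smallest index on ties
    nonzero = np.any(A != 0, axis=0)
    used = np.unique(raw[nonzero])
    component_map = {int(c): i for i, c in enumerate(used)}
    labels = np.full(A.shape[1], -1, dtype=np.int64)
    if used.size:
        remap = np.full(int(used.max()) + 1, -1, dtype=np.int64)
        remap[used] = np.arange(used.size)
        labels[nonzero] = remap[raw[nonzero]]
    return BucketAssignment(
        bucket_ids=np.asarray(bucket_ids, dtype=np.int64),
        labels=labels,
        n_clusters=used.size,
        component_map=component_map,
    )


def save_model(
    outdir: Path | str,
    dictionary: Dictionary,
    code: CodeMatrix,
    assignment: BucketAssignment,
) -> None:
    """Persist D and A as MatrixMarket files plus a JSON header, and the
    bucket assignment as TSV."""
    import json

    from scipy.io import mmwrite

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "dictionary.mtx"), dictionary.D)
    mmwrite(str(outdir / "codes.mtx"), sp.csc_matrix(code.coeffs))
    header = {
        "l1": dictionary.l1, "l2": dictionary.l2,
        "gamma1": dictionary.gamma1, "gamma2": dictionary.gamma2,
        "nonneg_dict": dictionary.nonneg_dict, "nonneg_code": dictionary.nonneg_code,
        "seed": dictionary.seed, "n_components": dictionary.n_components,
        "bucket_ids": code.bucket_ids.tolist(),
        "objective_history": dictionary.objective_history,
    }
    (outdir / "model.json").write_text(json.dumps(header))
    assignment.save_tsv(outdir / "buckets.tsv")


def load_model(outdir: Path | str) -> tuple[Dictionary, CodeMatrix, BucketAssignment]:
    import json

    from scipy.io import mmread

    outdir = Path(outdir)
    header = json.loads((outdir / "model.json").read_text())
    D = np.asarray(mmread(str(outdir / "dictionary.mtx")))
    A = np.asarray(sp.csc_matrix(mmread(str(outdir / "codes.mtx"))).todense())
    dictionary = Dictionary(
        D=D, l1=header["l1"], l2=header["l2"],
        gamma1=header["gamma1"], gamma2=header["gamma2"],
        nonneg_dict=header["nonneg_dict"], nonneg_code=header["nonneg_code"],
        seed=header["seed"], objective_history=list(header["objective_history"]),
    )
    code = CodeMatrix(coeffs=A, bucket_ids=np.asarray(header["bucket_ids"], dtype=np.int64))
    return dictionary, code, BucketAssignment.load_tsv(outdir / "buckets.tsv")


def factorize_matrix(
    matrix: AbundanceMatrix,
    p: int,
    **kwargs,
) -> tuple[Dictionary, CodeMatrix, BucketAssignment]:
    """End to end on an abundance matrix: learn, code occupied buckets, assign."""
    if not matrix.normalized:
        raise ValueError("matrix must be row-normalized first")
    occupied = matrix.occupied_buckets()
    Xo = matrix.matrix.tocsc()[:, occupied]
    dictionary = learn_dictionary(Xo, p, **kwargs)
    A = code_columns(Xo, dictionary)
    code = CodeMatrix(coeffs=A, bucket_ids=occupied)
    return dictionary, code, assign_buckets(code)
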