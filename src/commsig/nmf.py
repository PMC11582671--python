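"""Non-smooth NMF community partitioning and the signature-taxon index.

The abundance matrix V (taxa x samples) is factorised as V ~ W S H with
W >= 0 the basis (taxa x q), H >= 0 the coefficients (q x samples) and
S = (1 - theta) I + (theta / q) 11^T the smoothing matrix of non-smooth NMF
(theta in [0, 1]; theta = 0 recovers plain KL-divergence NMF).  Fitting uses
multiplicative Kullback-Leibler updates, which never increase the
objective.  Samples partition by their dominant descriptor (argmax column
of H).

Each taxon i is then scored against each descriptor k by three factors:

* rho_{i,k} — Spearman rank correlation between the taxon's abundance
  profile and descriptor k's coefficient profile across samples;
* Cos(theta)_{i,k} — cosine of the angle between the two profiles after
  unit normalization, sum_j a_{i,j} s_{k,j};
* Score(i) = 1 + (1/log2 q) * sum_k p(i,k) log2 p(i,k), one minus the
  normalized entropy of the taxon's basis-row distribution p(i, .): 1 for
  a taxon loading on a single descriptor, 0 for an undiscriminating one.

The index I_{i,k} = rho_{i,k} * Cos(theta)_{i,k} * Score(i); taxa whose
index exceeds a descriptor's mean by more than three standard deviations
are that descriptor's signature taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .containers import AbundanceTable

__all__ = [
    "NMFModel",
    "ASVIndexTable",
    "SignatureSet",
    "smoothing_matrix",
    "nsnmf_fit",
    "nsnmf_best_of",
    "rank_survey",
    "cosine_projection",
    "entropy_score",
    "spearman_rho",
    "asv_index",
    "select_signatures",
]

_EPS = 1e-12


def smoothing_matrix(q: int, theta: float) -> np.ndarray:
    """S = (1 - theta) I + (theta / q) 11^T."""
    if not 0 <= theta <= 1:
        raise ValueError("theta must lie in [0, 1]")
    return (1 - theta) * np.eye(q) + (theta / q) * np.ones((q, q))


@dataclass
class NMFModel:
    """Fitted non-smooth NMF decomposition V ~ W S H."""

    W: pd.DataFrame          # taxa x q basis
    H: pd.DataFrame          # q x samples coefficients
    theta: float
    objective_trace: np.ndarray
    seed: int
    n_iter: int
    converged: bool

    @property
    def q(self) -> int:
        return self.W.shape[1]

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    @property
    def smoothing(self) -> np.ndarray:
        return smoothing_matrix(self.q, self.theta)

    def reconstruction(self) -> np.ndarray:
        return self.W.to_numpy() @ self.smoothing @ self.H.to_numpy()

    def sample_assignments(self) -> pd.Series:
        """Dominant descriptor per sample (argmax of H columns)."""
        H = self.H.to_numpy()
        return pd.Series(
            [self.H.index[i] for i in H.argmax(axis=0)], index=self.H.columns
        )


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    WH = np.maximum(WH, _EPS)
    return float((V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum())


def _validate_v(V: np.ndarray, q: int) -> None:
    if (V < 0).any():
        raise ValueError("V contains negative entries")
    if (V.sum(axis=1) == 0).any():
        raise ValueError("V has all-zero rows; drop empty taxa first")
    if (V.sum(axis=0) == 0).any():
        raise ValueError("V has all-zero columns; drop empty samples first")
    if not 2 <= q or q >= min(V.shape):
        if q != 1:  # rank-1 allowed for degenerate exact-factorization checks
            raise ValueError("rank must satisfy 2 <= q < min(n_taxa, n_samples)")


def nsnmf_fit(
    V: AbundanceTable | pd.DataFrame | np.ndarray,
    q: int,
    theta: float = 0.5,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> NMFModel:
    """Fit V ~ W S H by multiplicative KL updates.

    H is updated against the effective basis W S and W against the
    effective coefficients S H, so each half-step is a standard KL update
    and the objective never increases.  Initialization is uniform random
    scaled to V's mean; stops when the relative objective change drops
    below ``tol``.
    """
    taxa, samples, Va = _as_matrix(V)
    _validate_v(Va, q)
    S = smoothing_matrix(q, theta)
    rng = np.random.default_rng(seed)
    scale = np.sqrt(Va.mean() / q)
    W = rng.uniform(0, 1, size=(Va.shape[0], q)) * scale
    H = rng.uniform(0, 1, size=(q, Va.shape[1])) * scale

    trace = [np.inf]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # update H with effective basis A = W S
        A = W @ S
        WH = np.maximum(A @ H, _EPS)
        H *= (A.T @ (Va / WH)) / np.maximum(A.sum(axis=0)[:, None], _EPS)
        # update W with effective coefficients B = S H
        B = S @ H
        WH = np.maximum(W @ B, _EPS)
        W *= ((Va / WH) @ B.T) / np.maximum(B.sum(axis=1)[None, :], _EPS)
        obj = _kl_divergence(Va, W @ S @ H)
        trace.append(obj)
        prev = trace[-2]
        if np.isfinite(prev) and prev - obj <= tol * max(abs(prev), 1.0):
            converged = True
            break
    return NMFModel(
        pd.DataFrame(W, index=taxa, columns=[f"D{k + 1}" for k in range(q)]),
        pd.DataFrame(H, index=[f"D{k + 1}" for k in range(q)], columns=samples),
        theta,
        np.asarray(trace[1:]),
        seed,
        it,
        converged,
    )


def _as_matrix(V) -> tuple[list[str], list[str], np.ndarray]:
    if isinstance(V, AbundanceTable):
        return V.taxa_ids, V.sample_ids, V.counts.astype(float)
    if isinstance(V, pd.DataFrame):
        return list(V.index), list(V.columns), V.to_numpy(dtype=float)
    V = np.asarray(V, dtype=float)
    return (
        [f"t{i}" for i in range(V.shape[0])],
        [f"s{j}" for j in range(V.shape[1])],
        V,
    )


@dataclass
class MultiRunResult:
    best: NMFModel
    objectives: np.ndarray
    agreement: float            # mean ARI of each run's partition vs the best run's


def nsnmf_best_of(
    V,
    q: int,
    n_runs: int = 200,
    theta: float = 0.5,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> MultiRunResult:
    """Best-objective fit over ``n_runs`` independently seeded runs.

    Also reports every run's final objective and the mean adjusted-Rand
    agreement of each run's dominant-descriptor sample partition with the
    best run's partition.
    """
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=n_runs)
    models = [
        nsnmf_fit(V, q, theta=theta, seed=int(s), max_iter=max_iter, tol=tol)
        for s in seeds
    ]
    objectives = np.array([m.objective for m in models])
    best = models[int(np.argmin(objectives))]
    ref = best.sample_assignments().to_numpy()
    aris = [
        adjusted_rand_score(ref, m.sample_assignments().to_numpy()) for m in models
    ]
    return MultiRunResult(best, objectives, float(np.mean(aris)))


def rank_survey(
    V,
    ranks=range(3, 8),
    n_runs: int = 100,
    theta: float = 0.5,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Per-rank diagnostics: best KL objective and cophenetic correlation
    of the run-consensus sample co-assignment matrix."""
    rng = np.random.default_rng(seed)
    rows = []
    for q in ranks:
        seeds = rng.integers(2**31, size=n_runs)
        models = [
            nsnmf_fit(V, q, theta=theta, seed=int(s), max_iter=max_iter, tol=tol)
            for s in seeds
        ]
        objs = np.array([m.objective for m in models])
        n_samples = models[0].H.shape[1]
        C = np.zeros((n_samples, n_samples))
        for m in models:
            a = m.H.to_numpy().argmax(axis=0)
            C += a[:, None] == a[None, :]
        C /= n_runs
        dist = 1.0 - C
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        coph, _ = cophenet(Z, squareform(dist, checks=False))
        rows.append({"rank": q, "best_objective": float(objs.min()),
                     "cophenetic": float(coph)})
    return pd.DataFrame(rows).set_index("rank")


# ---------------------------------------------------------------------------
# The three-factor taxon index
# ---------------------------------------------------------------------------

def cosine_projection(a_i, s_k) -> float:
    """Cosine of the angle between two profiles (dot of unit vectors)."""
    a = np.asarray(a_i, dtype=float)
    s = np.asarray(s_k, dtype=float)
    na, ns = np.linalg.norm(a), np.linalg.norm(s)
    if na == 0 or ns == 0:
        raise ValueError("zero vector has no direction")
    return float((a / na) @ (s / ns))


def entropy_score(p) -> float:
    """1 minus the normalized (log2) entropy of a probability vector."""
    p = np.asarray(p, dtype=float)
    q = len(p)
    if q < 2:
        raise ValueError("need at least 2 descriptors")
    if (p < 0).any() or not np.isclose(p.sum(), 1.0):
        raise ValueError("p must be a probability vector")
    nz = p[p > 0]
    return float(1.0 + (nz * np.log2(nz)).sum() / np.log2(q))


def spearman_rho(a_i, h_k) -> float:
    """Spearman rank correlation (mean ranks for ties)."""
    a = np.asarray(a_i, dtype=float)
    h = np.asarray(h_k, dtype=float)
    if len(a) != len(h):
        raise ValueError("length mismatch")
    if len(a) < 3:
        raise ValueError("need at least 3 samples")
    if np.allclose(a, a[0]) or np.allclose(h, h[0]):
        warnings.warn("constant profile; Spearman rho set to 0", stacklevel=2)
        return 0.0
    ra = scipy.stats.rankdata(a)
    rh = scipy.stats.rankdata(h)
    return float(np.corrcoef(ra, rh)[0, 1])


@dataclass
class ASVIndexTable:
    """Per-(taxon, descriptor) index components and totals."""

    rho: pd.DataFrame          # taxa x descriptors
    cos_theta: pd.DataFrame
    score: pd.Series           # per taxon
    index: pd.DataFrame        # rho * cos_theta * score

    def descriptor_moments(self) -> pd.DataFrame:
        """Per-descriptor mean and sample sd of the index."""
        return pd.DataFrame(
            {"mean": self.index.mean(axis=0), "sd": self.index.std(axis=0, ddof=1)}
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (taxon, descriptor, rho, cos_theta, score, index)."""
        out = []
        for k in self.index.columns:
            out.append(
                pd.DataFrame(
                    {
                        "taxon_id": self.index.index,
                        "descriptor": k,
                        "rho": self.rho[k].to_numpy(),
                        "cos_theta": self.cos_theta[k].to_numpy(),
                        "score": self.score.to_numpy(),
                        "index": self.index[k].to_numpy(),
                    }
                )
            )
        return pd.concat(out, ignore_index=True)


def asv_index(table: AbundanceTable | pd.DataFrame, model: NMFModel) -> ASVIndexTable:
    """Compute rho, cosine projection and entropy score for every
    (taxon, descriptor) pair, and their product, the taxon index.

    ``table`` must be the matrix the model was fitted to (same taxa and
    samples).  Taxa with an all-zero basis row get Score 0 (index 0) with a
    warning; constant abundance profiles get rho 0.
    """
    taxa, samples, A = _as_matrix(table)
    if list(model.W.index) != taxa or list(model.H.columns) != samples:
        raise ValueError("table and model do not share taxa/samples")
    H = model.H.to_numpy()
    W = model.W.to_numpy()
    q = model.q
    desc = list(model.H.index)

    # Spearman rho via ranked Pearson, vectorized over taxa
    rank_a = np.apply_along_axis(scipy.stats.rankdata, 1, A)
    rank_h = np.apply_along_axis(scipy.stats.rankdata, 1, H)
    const_taxa = np.isclose(A.std(axis=1), 0)
    if const_taxa.any():
        warnings.warn(
            f"{int(const_taxa.sum())} constant taxon profiles; rho set to 0",
            stacklevel=2,
        )
    ra = rank_a - rank_a.mean(axis=1, keepdims=True)
    rh = rank_h - rank_h.mean(axis=1, keepdims=True)
    denom = np.outer(
        np.linalg.norm(ra, axis=1), np.linalg.norm(rh, axis=1)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (ra @ rh.T) / denom, 0.0)
    rho[const_taxa] = 0.0

    # cosine projection on unit-normalized profiles
    na = np.linalg.norm(A, axis=1)
    nh = np.linalg.norm(H, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (A @ H.T) / np.outer(np.where(na > 0, na, 1), np.where(nh > 0, nh, 1))
    cos[na == 0] = 0.0

    # entropy score from row-normalized basis
    wsum = W.sum(axis=1)
    zero_rows = wsum == 0
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} taxa have an all-zero basis row; Score = 0",
            stacklevel=2,
        )
    P = W / np.where(wsum > 0, wsum, 1)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(P > 0, P * np.log2(np.maximum(P, _EPS)), 0.0)
    score = 1.0 + plogp.sum(axis=1) / np.log2(q)
    score = np.clip(score, 0.0, 1.0)
    score[zero_rows] = 0.0

    index = rho * cos * score[:, None]
    ti = pd.Index(taxa, name="taxon_id")
    return ASVIndexTable(
        pd.DataFrame(rho, index=ti, columns=desc),
        pd.DataFrame(cos, index=ti, columns=desc),
        pd.Series(score, index=ti, name="score"),
        pd.DataFrame(index, index=ti, columns=desc),
    )


@dataclass
class SignatureSet:
    """Signature taxa per descriptor with the 3-SD thresholds used."""

    signatures: dict[str, pd.Series]      # descriptor -> index values of signatures
    thresholds: pd.Series                  # descriptor -> mean + 3 sd
    moments: pd.DataFrame                  # descriptor -> (mean, sd)

    def taxa(self, descriptor: str) -> list[str]:
        return list(self.signatures[descriptor].index)

    def all_taxa(self) -> set[str]:
        return {t for s in self.signatures.values() for t in s.index}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, s in self.signatures.items():
            for t, v in s.items():
                rows.append({"descriptor": k, "taxon_id": t, "index": v})
        return pd.DataFrame(rows, columns=["descriptor", "taxon_id", "index"])


def select_signatures(idx: ASVIndexTable) -> SignatureSet:
    """Signature taxa: index strictly above a descriptor's mean + 3 sd.

    The mean and sample (n-1) standard deviation are taken over all taxa
    within each descriptor column.
    """
    if idx.index.shape[0] < 2:
        raise ValueError("need at least 2 taxa")
    moments = idx.descriptor_moments()
    thresholds = moments["mean"] + 3 * moments["sd"]
    sigs = {}
    for k in idx.index.columns:
        col = idx.index[k]
        sel = col[col > thresholds[k]].sort_values(ascending=False)
        sigs[k] = sel
    return SignatureSet(sigs, thresholds, moments)
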