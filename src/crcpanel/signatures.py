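"""96-context mutational-signature machinery.

Single-base substitutions are classified into the standard 96 channels:
6 pyrimidine-reference substitution types (C>A, C>G, C>T, T>A, T>C, T>G)
x 16 flanking-base pairs.  De-novo signatures are extracted with
Kullback-Leibler multiplicative-update NMF; observed donor spectra are
deconvolved against a reference catalog by floor-and-refit constrained
least squares (weights nonnegative, summing to at most one; components
below a weight floor are zeroed and the fit re-solved).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io import VariantRecord, VariantType

__all__ = [
    "CHANNELS_96",
    "classify_96",
    "channel_to_snv",
    "ContextMatrix",
    "build_context_matrix",
    "SignatureCatalog",
    "reference_catalog",
    "read_catalog",
    "write_catalog",
    "extract_signatures",
    "NMFResult",
    "ExposureResult",
    "deconvolve",
    "rank_survey",
]

_SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _build_channels() -> list[str]:
    labels = []
    for sub in _SUBSTITUTIONS:
        ref = sub[0]
        for five in _BASES:
            for three in _BASES:
                labels.append(f"{five}[{sub}]{three}")
    return labels


#: canonical channel order: substitution-major, then 5' flank, then 3' flank
CHANNELS_96: list[str] = _build_channels()
_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS_96)}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def classify_96(variant: VariantRecord) -> int:
    """Map an SNV with context to its channel index (0..95).

    Purine-reference substitutions are folded onto the pyrimidine strand by
    reverse complement before lookup.

    Raises ``ValueError`` for indels or missing context (callers count these
    as unclassifiable).
    """
    if variant.variant_type is not VariantType.SNP:
        raise ValueError("only SNVs are classifiable into the 96 channels")
    if variant.context3 is None:
        raise ValueError("context3 required for 96-channel classification")
    ref, alt, ctx = variant.ref, variant.alt, variant.context3
    if ref in "AG":  # fold to pyrimidine reference
        ref, alt, ctx = _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(ctx)
    return _CHANNEL_INDEX[f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"]


def channel_to_snv(channel: int) -> tuple[str, str, str]:
    """Inverse of :func:`classify_96` on the pyrimidine strand: (ref, alt, context3)."""
    label = CHANNELS_96[channel]
    return label[2], label[4], label[0] + label[2] + label[6]


@dataclass
class ContextMatrix:
    """Donor x 96 mutation-count matrix in the canonical channel order."""

    donors: list[str]
    counts: np.ndarray  # shape (n_donors, 96), nonnegative integers
    n_unclassifiable: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.donors), 96):
            raise ValueError("counts must be donors x 96")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.donors, columns=CHANNELS_96)


def build_context_matrix(
    variants: Sequence[VariantRecord], donors: Sequence[str] | None = None
) -> ContextMatrix:
    """Tally classifiable SNVs per donor into the 96 channels.

    Indels and SNVs lacking context are excluded; their number is reported in
    ``n_unclassifiable``.
    """
    if donors is None:
        donors = []
        for v in variants:
            if v.donor_id not in donors:
                donors.append(v.donor_id)
    index = {d: i for i, d in enumerate(donors)}
    counts = np.zeros((len(donors), 96), dtype=int)
    skipped = 0
    for v in variants:
        if v.donor_id not in index:
            continue
        try:
            counts[index[v.donor_id], classify_96(v)] += 1
        except ValueError:
            skipped += 1
    return ContextMatrix(list(donors), counts, n_unclassifiable=skipped)


@dataclass
class SignatureCatalog:
    """96 x K nonnegative matrix; each signature column sums to one."""

    names: list[str]
    matrix: np.ndarray  # shape (96, K)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError("matrix must be 96 x K")
        if (self.matrix < 0).any():
            raise ValueError("signatures must be nonnegative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("signature columns must sum to 1")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=CHANNELS_96, columns=self.names)


def _peaked_profile(peaks: dict[str, float], background: float) -> np.ndarray:
    profile = np.full(96, background)
    for label, weight in peaks.items():
        profile[_CHANNEL_INDEX[label]] += weight
    return profile / profile.sum()


def reference_catalog() -> SignatureCatalog:
    """Bundled synthetic K=5 reference catalog with distinct, documented profiles.

    The five components caricature processes relevant to colorectal tumors
    without reproducing any licensed catalog verbatim:

    - ``clock_cpg``      spontaneous-deamination clock: C>T at NpCpG contexts.
    - ``mmr_deficient``  mismatch-repair failure: broad C>T plus T>C.
    - ``pole_exo``       polymerase-epsilon proofreading loss: dominant C>A
      at TpCpT (plus minor T>G at TpTpT), the ultra-hypermutator pattern.
    - ``apobec_like``    C>T / C>G restricted to TpCpN contexts.
    - ``flat``           uniform background over all 96 channels.
    """
    catalog = {}
    catalog["clock_cpg"] = _peaked_profile(
        {f"{five}[C>T]G": 1.0 for five in _BASES}, background=0.02
    )
    mmr_peaks = {f"{five}[C>T]{three}": 0.25 for five in _BASES for three in _BASES}
    mmr_peaks.update({f"{five}[T>C]{three}": 0.15 for five in _BASES for three in _BASES})
    catalog["mmr_deficient"] = _peaked_profile(mmr_peaks, background=0.01)
    catalog["pole_exo"] = _peaked_profile({"T[C>A]T": 10.0, "T[T>G]T": 2.0}, background=0.02)
    catalog["apobec_like"] = _peaked_profile(
        {f"T[C>T]{t}": 1.0 for t in _BASES} | {f"T[C>G]{t}": 1.0 for t in _BASES},
        background=0.01,
    )
    catalog["flat"] = np.full(96, 1.0 / 96)
    names = list(catalog)
    return SignatureCatalog(names, np.column_stack([catalog[n] for n in names]))


def read_catalog(path: str | Path) -> SignatureCatalog:
    """Read a catalog TSV: 96 rows in canonical channel order, one column per signature."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != CHANNELS_96:
        raise ValueError("catalog rows must be the 96 channels in canonical order")
    return SignatureCatalog(list(df.columns), df.to_numpy(dtype=float))


def write_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index_label="channel")


# ---------------------------------------------------------------------------
# NMF extraction
# ---------------------------------------------------------------------------

@dataclass
class NMFResult:
    signatures: np.ndarray      # 96 x k, columns sum to 1
    exposures: np.ndarray       # donors x k (counts scale)
    reconstruction_error: float  # generalized KL divergence at convergence
    objective_trace: list[float] = field(default_factory=list)


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    eps = 1e-12
    mask = V > 0
    return float(
        (V[mask] * np.log(V[mask] / np.maximum(WH[mask], eps))).sum()
        - V.sum() + WH.sum()
    )


def _nmf_kl_single(
    V: np.ndarray, k: int, rng: np.random.Generator,
    max_iter: int, tol: float,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """One multiplicative-update run minimizing generalized KL divergence."""
    n, m = V.shape
    scale = np.sqrt(V.mean() / k)
    W = scale * (0.5 + rng.random((n, k)))
    H = scale * (0.5 + rng.random((k, m)))
    eps = 1e-12
    trace = [_kl_divergence(V, W @ H)]
    for it in range(max_iter):
        WH = np.maximum(W @ H, eps)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], eps)
        WH = np.maximum(W @ H, eps)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], eps)
        obj = _kl_divergence(V, W @ H)
        trace.append(obj)
        prev = trace[-2]
        if prev - obj < tol * max(abs(prev), 1.0):
            break
    return W, H, trace


def extract_signatures(
    matrix: ContextMatrix,
    k: int,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> NMFResult:
    """De-novo signature extraction by KL multiplicative-update NMF.

    Runs ``n_restarts`` random initializations and keeps the run with the
    lowest final objective.  Signature columns are normalized to sum to one,
    with exposures rescaled compensatingly, so exposures stay on the
    mutation-count scale.
    """
    V = np.asarray(matrix.counts, dtype=float)
    if k < 1 or k > min(V.shape):
        raise ValueError(f"k={k} outside [1, {min(V.shape)}]")
    if not V.any():
        raise ValueError("context matrix is all zero")
    root = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(n_restarts):
        W, H, trace = _nmf_kl_single(V, k, root, max_iter, tol)
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace)
    W, H, trace = best
    col_sums = H.sum(axis=1)  # per-signature channel mass
    col_sums[col_sums == 0] = 1.0
    signatures = (H / col_sums[:, None]).T          # 96 x k
    exposures = W * col_sums[None, :]               # donors x k
    return NMFResult(signatures, exposures, trace[-1], trace)


def rank_survey(
    matrix: ContextMatrix,
    k_values: Sequence[int],
    n_restarts: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Reconstruction error and restart-consistency across candidate ranks.

    Reports, per k: the best KL objective and the mean pairwise cosine
    similarity of matched signatures across restarts (a stability proxy).
    The choice of k remains the caller's.
    """
    rows = []
    for k in k_values:
        V = np.asarray(matrix.counts, dtype=float)
        root = np.random.default_rng(seed + k)
        runs = []
        for _ in range(n_restarts):
            W, H, trace = _nmf_kl_single(V, k, root, 500, 1e-6)
            sums = H.sum(axis=1, keepdims=True)
            sums[sums == 0] = 1.0
            runs.append((H / sums, trace[-1]))
        best_obj = min(obj for _, obj in runs)
        sims = []
        for i in range(len(runs)):
            for j in range(i + 1, len(runs)):
                sims.append(_matched_cosine(runs[i][0], runs[j][0]))
        rows.append({"k": k, "best_objective": best_obj,
                     "restart_consistency": float(np.mean(sims)) if sims else 1.0})
    return pd.DataFrame(rows)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _matched_cosine(H1: np.ndarray, H2: np.ndarray) -> float:
    """Greedy best-match mean cosine between two k x 96 signature sets."""
    k = H1.shape[0]
    sim = np.array([[cosine_similarity(H1[i], H2[j]) for j in range(k)] for i in range(k)])
    total, used = 0.0, set()
    for i in range(k):
        j = int(np.argmax([sim[i, j] if j not in used else -np.inf for j in range(k)]))
        used.add(j)
        total += sim[i, j]
    return total / k


# ---------------------------------------------------------------------------
# Deconvolution against a reference catalog
# ---------------------------------------------------------------------------

@dataclass
class ExposureResult:
    donor_id: str
    weights: dict[str, float]
    unassigned: float
    reconstruction_error: float


def _constrained_fit(profile: np.ndarray, S: np.ndarray) -> np.ndarray:
    """min ||profile - S w||^2 s.t. w >= 0, sum(w) <= 1."""
    k = S.shape[1]
    if k == 0:
        return np.zeros(0)

    def objective(w):
        r = S @ w - profile
        return r @ r

    def gradient(w):
        return 2.0 * S.T @ (S @ w - profile)

    w0 = np.full(k, min(1.0 / k, 0.9 / k))
    res = minimize(
        objective, w0, jac=gradient, method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "ineq", "fun": lambda w: 1.0 - w.sum(),
                      "jac": lambda w: -np.ones_like(w)}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    return np.clip(res.x, 0.0, None)


def deconvolve(
    donor_counts: np.ndarray,
    catalog: SignatureCatalog,
    weight_floor: float = 0.06,
    donor_id: str = "",
) -> ExposureResult:
    """Express a donor's 96-channel spectrum as a nonnegative mixture of
    reference signatures.

    The donor profile is normalized to sum 1 and fit by least squares with
    weights >= 0 and sum(weights) <= 1.  Components whose weight falls below
    ``weight_floor`` are zeroed and the fit is re-solved on the survivors
    (iterated to a fixed point).  ``unassigned`` is the weight mass not
    attributed to any reference signature.
    """
    counts = np.asarray(donor_counts, dtype=float)
    if counts.shape != (96,):
        raise ValueError("donor_counts must be a 96-vector")
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot deconvolve a zero-count donor")
    profile = counts / total
    S = catalog.matrix
    active = list(range(S.shape[1]))
    while True:
        w_active = _constrained_fit(profile, S[:, active])
        below = [i for i, w in zip(active, w_active) if w < weight_floor]
        if not below or len(below) == len(active):
            if below and len(below) == len(active):
                active, w_active = [], np.zeros(0)
            break
        active = [i for i in active if i not in below]
    weights = np.zeros(S.shape[1])
    for i, w in zip(active, w_active):
        weights[i] = w
    residual = S @ weights - profile
    return ExposureResult(
        donor_id=donor_id,
        weights={name: float(w) for name, w in zip(catalog.names, weights)},
        unassigned=float(1.0 - weights.sum()),
        reconstruction_error=float(residual @ residual),
    )
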