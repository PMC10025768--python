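"""Novel cell-type perception: ensemble uncertainty, bimodality tests, and
the adaptive manifold-mixup partition threshold.

Each target cell gets an E-score built from three complementary readings of
the frozen source classifiers at its latent embedding z:

* EN, the prediction entropy of the main classifier (insensitive near both
  the uniform and the one-hot extremes, hence not used alone);
* CF, the confidence (maximum class probability);
* CS, the consistency (inner product of the two auxiliary classifiers'
  probability vectors - robust to batch-shift-induced overconfidence, since
  two independently initialized heads rarely agree on the same wrong class).

E-score = (1 - EN/log K + CF + CS) / 3 in [0, 1]; high means "known".

Whether novel cell types are present at all is decided by testing the
E-score distribution for bimodality: the bimodality coefficient
(g1^2 + 1) / (g2 + 3(n-1)^2 / ((n-2)(n-3))) against the uniform benchmark
5/9, OR Hartigan's dip test at level 0.05.  Either test firing counts as
detection.

If novelty is detected, the partition threshold delta is the mean E-score of
manifold-mixup points lam * z_i + (1 - lam) * z_j over pairs i != j: random
convex combinations of two cells imitate "novel-like" representations, so
their average certainty adapts to how much of the data is novel.  Cells with
E-score strictly above delta are "known" (ties go to "unknown").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import stats as sps

from .dip import dip_test

BC_UNIFORM_BENCHMARK = 5.0 / 9.0


@dataclass
class EScoreReport:
    """Per-cell uncertainty components and the combined E-score."""

    EN: np.ndarray
    CF: np.ndarray
    CS: np.ndarray
    e_score: np.ndarray
    K: int


@dataclass
class BimodalityResult:
    bc_value: float
    bc_threshold: float
    dip_statistic: float
    dip_pvalue: float
    alpha_dip: float
    novel_detected: bool

    def to_dict(self) -> dict:
        return {
            "bc_value": self.bc_value,
            "bc_threshold": self.bc_threshold,
            "dip_statistic": self.dip_statistic,
            "dip_pvalue": self.dip_pvalue,
            "alpha_dip": self.alpha_dip,
            "novel_detected": self.novel_detected,
        }


@dataclass
class Partition:
    """Threshold delta and the known/unknown index sets."""

    delta: Optional[float]
    known_idx: np.ndarray
    unknown_idx: np.ndarray


def _check_probs(p: np.ndarray, K: int, name: str):
    if p.shape[-1] != K:
        raise ValueError(f"{name} must have {K} columns")
    if np.abs(p.sum(axis=-1) - 1.0).max() > 1e-4:
        raise ValueError(f"{name} rows must sum to 1 within 1e-4")


def e_score_components(p, p1, p2, K: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Entropy, confidence and consistency from the three classifier outputs."""
    p, p1, p2 = (np.atleast_2d(np.asarray(a, dtype=np.float64)) for a in (p, p1, p2))
    for a, name in ((p, "p"), (p1, "p1"), (p2, "p2")):
        _check_probs(a, K, name)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    EN = -plogp.sum(axis=-1)
    CF = p.max(axis=-1)
    CS = (p1 * p2).sum(axis=-1)
    return EN, CF, CS


def e_score(EN, CF, CS, K: int) -> np.ndarray:
    """Combine the three components; higher means more certainly 'known'."""
    if K < 2:
        raise ValueError("E-score normalization needs K >= 2")
    EN, CF, CS = (np.asarray(a, dtype=np.float64) for a in (EN, CF, CS))
    return (1.0 - EN / np.log(K) + CF + CS) / 3.0


def escore_report(p, p1, p2, K: int) -> EScoreReport:
    EN, CF, CS = e_score_components(p, p1, p2, K)
    return EScoreReport(EN=EN, CF=CF, CS=CS, e_score=e_score(EN, CF, CS, K), K=K)


def bimodality_coefficient(samples) -> float:
    """Sample bimodality coefficient (bias-corrected skewness/kurtosis form)."""
    x = np.asarray(samples, dtype=np.float64)
    n = len(x)
    if n < 4:
        raise ValueError("bimodality coefficient needs at least 4 observations")
    if np.ptp(x) == 0 or x.std() == 0:
        warnings.warn("zero-variance sample; bimodality coefficient defined as 0", stacklevel=2)
        return 0.0
    g1 = sps.skew(x, bias=False)
    g2 = sps.kurtosis(x, fisher=True, bias=False)
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def detect_novelty(
    escores,
    alpha_dip: float = 0.05,
    bc_threshold: float = BC_UNIFORM_BENCHMARK,
    n_boot: int = 200,
    seed: int = 0,
) -> BimodalityResult:
    """OR-rule over the bimodality coefficient and the dip test."""
    x = np.asarray(escores, dtype=np.float64)
    if len(x) < 10:
        raise ValueError("novelty detection needs at least 10 cells")
    bc = bimodality_coefficient(x)
    d, p = dip_test(x, n_boot=n_boot, seed=seed)
    return BimodalityResult(
        bc_value=bc,
        bc_threshold=bc_threshold,
        dip_statistic=d,
        dip_pvalue=p,
        alpha_dip=alpha_dip,
        novel_detected=bool(bc > bc_threshold or p < alpha_dip),
    )


_EXACT_LIMIT = 1500  # enumerate all ordered pairs up to this many cells


def mixup_threshold(
    R: np.ndarray,
    heads: Callable[[np.ndarray], Tuple[np.ndarray, np.ndarray, np.ndarray]],
    n_pairs="auto",
    seed: int = 0,
    lambdas=None,
) -> float:
    """Mean E-score of latent mixtures lam*z_i + (1-lam)*z_j, i != j.

    ``heads`` maps a latent matrix to the (p, p1, p2) softmax outputs of the
    frozen classifier ensemble.  All ordered pairs are enumerated when the
    bank is small (or ``n_pairs='all'``); otherwise a seeded Monte-Carlo
    subsample of ``n_pairs`` pairs is used (default 50 per cell).
    ``lambdas`` overrides the Uniform(0,1) mixing draws (testing hook).
    """
    R = np.asarray(R, dtype=np.float64)
    nt = R.shape[0]
    if nt < 2:
        raise ValueError("mixup threshold needs at least 2 cells")
    rng = np.random.default_rng(seed)
    if n_pairs == "auto":
        n_pairs = "all" if nt <= _EXACT_LIMIT else 50 * nt
    if n_pairs == "all":
        ii, jj = np.meshgrid(np.arange(nt), np.arange(nt), indexing="ij")
        mask = ii != jj
        ii, jj = ii[mask], jj[mask]
    else:
        n_pairs = int(n_pairs)
        ii = rng.integers(0, nt, size=n_pairs)
        jj = rng.integers(0, nt - 1, size=n_pairs)
        jj = np.where(jj >= ii, jj + 1, jj)  # exclude i == j
    lam = np.asarray(lambdas, dtype=np.float64) if lambdas is not None else rng.random(len(ii))
    lam = np.broadcast_to(lam, (len(ii),))

    total, count = 0.0, 0
    chunk = 200_000
    for start in range(0, len(ii), chunk):
        sl = slice(start, start + chunk)
        zmix = lam[sl, None] * R[ii[sl]] + (1.0 - lam[sl, None]) * R[jj[sl]]
        p, p1, p2 = heads(zmix)
        K = p.shape[1]
        rep = escore_report(p, p1, p2, K)
        total += float(rep.e_score.sum())
        count += len(rep.e_score)
    return total / count


def partition(escores, delta: Optional[float], novel_detected: bool) -> Partition:
    """Known/unknown split: strictly above delta is 'known'; ties are 'unknown'.

    Without detected novelty every cell is 'known' and delta is undefined.
    """
    x = np.asarray(escores, dtype=np.float64)
    n = len(x)
    if not novel_detected:
        return Partition(delta=None, known_idx=np.arange(n), unknown_idx=np.array([], dtype=int))
    known = np.where(x > delta)[0]
    unknown = np.where(x <= delta)[0]
    return Partition(delta=float(delta), known_idx=known, unknown_idx=unknown)
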