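"""Exploratory connectivity and regional fractal-dynamics contrasts.

DCCC networks (detrended cross-correlation coefficients between all channel
pairs, averaged over epochs of one class) capture fractal functional
connectivity; class contrasts test each connection with a paired t-test or
Wilcoxon signed-rank test depending on a Lilliefors normality screen, and
sort significant connections into three categories: positive in both
classes, negative in both, or sign-flipping between classes.  Regional
dynamics are summarised per channel by the DFA scaling exponent of
broadband-filtered activity (dyadic scales 16-256, profile step included)
and contrasted the same way.  P-values are deliberately unadjusted: the
analyses are exploratory.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .fractal import ScaleSpec, dcca_matrix, dfa_exponent

__all__ = [
    "dccc_matrix",
    "dccc_network",
    "contrast_connections",
    "dfa_topography",
]

DYADIC_SCALES = (16, 32, 64, 128, 256)


def dccc_matrix(epoch: np.ndarray, spec: ScaleSpec) -> np.ndarray:
    """DCCC coefficient matrix of one epoch (diagonal exactly 1)."""
    f2 = dcca_matrix(epoch, spec)
    d = np.sqrt(np.diag(f2))
    rho = f2 / np.outer(d, d)
    rho = np.clip(0.5 * (rho + rho.T), -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def dccc_network(epochs, s: int = 128, mode: str = "sliding") -> np.ndarray:
    """Mean DCCC matrix over the epochs of one class (one subject)."""
    epochs = list(epochs)
    if not epochs:
        raise ValueError("need at least one epoch")
    spec = ScaleSpec(s=s, mode=mode)
    nets = [dccc_matrix(np.asarray(e, dtype=float), spec) for e in epochs]
    return np.mean(nets, axis=0)


def _paired_test(a: np.ndarray, b: np.ndarray, alpha: float = 0.05):
    """Normality-routed paired test; returns (test_name, p_value)."""
    d = a - b
    if np.allclose(d, 0.0):
        return "t", 1.0
    use_t = True
    if d.size >= 4:
        try:
            _, lp = _lilliefors(d, dist="norm")
            use_t = lp >= alpha
        except (ValueError, ZeroDivisionError):
            use_t = True
    if use_t:
        _, p = stats.ttest_rel(a, b)
        return "t", float(p)
    method = "exact" if (d.size <= 25 and not np.any(d == 0)) else "approx"
    _, p = stats.wilcoxon(d, method=method)
    return "wilcoxon", float(p)


def contrast_connections(
    networks_a: np.ndarray,
    networks_b: np.ndarray,
    alpha: float = 0.05,
    ch_names=None,
) -> pd.DataFrame:
    """Connection-wise contrast of per-subject DCCC networks between classes.

    ``networks_a`` / ``networks_b`` are (n_subjects, n, n) stacks, paired by
    subject.  Each upper-triangle connection is tested (t or Wilcoxon after
    a Lilliefors screen) at unadjusted ``alpha``; significant connections
    are categorised from the group-mean coefficient signs:
    ``positive_both``, ``negative_both``, or ``sign_flip``.
    """
    a = np.asarray(networks_a, dtype=float)
    b = np.asarray(networks_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3 or a.shape[1] != a.shape[2]:
        raise ValueError("need matching (n_subjects, n, n) stacks")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 subjects for a paired contrast")
    n = a.shape[1]
    names = ch_names if ch_names is not None else [f"ch{i}" for i in range(n)]
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            test, p = _paired_test(a[:, i, j], b[:, i, j], alpha)
            mean_a = float(a[:, i, j].mean())
            mean_b = float(b[:, i, j].mean())
            significant = p < alpha
            if not significant:
                category = None
            elif mean_a >= 0 and mean_b >= 0:
                category = "positive_both"
            elif mean_a < 0 and mean_b < 0:
                category = "negative_both"
            else:
                category = "sign_flip"
            rows.append(
                {
                    "connection": f"{names[i]}-{names[j]}",
                    "i": i,
                    "j": j,
                    "test": test,
                    "p": p,
                    "mean_a": mean_a,
                    "mean_b": mean_b,
                    "significant": significant,
                    "category": category,
                }
            )
    return pd.DataFrame(rows)


def dfa_topography(
    epochs_a,
    epochs_b,
    scales=DYADIC_SCALES,
    alpha: float = 0.05,
    ch_names=None,
) -> pd.DataFrame:
    """Per-channel DFA exponents per class with paired contrasts.

    ``epochs_a`` / ``epochs_b``: per-subject lists of (n_channels, n_samples)
    epochs for the two classes (broadband-filtered; epochs must be at least
    as long as the largest scale).  Each subject contributes the mean
    exponent over epochs per channel; channels are contrasted with the same
    normality-routed paired test as connections.
    """
    scales = tuple(int(s) for s in scales)

    def subject_alphas(subject_epochs):
        eps = [np.asarray(e, dtype=float) for e in subject_epochs]
        if not eps:
            raise ValueError("each subject needs at least one epoch")
        n_ch = eps[0].shape[0]
        if any(e.shape[1] < max(scales) for e in eps):
            raise ValueError(f"epochs must have at least {max(scales)} samples")
        out = np.empty(n_ch)
        for c in range(n_ch):
            vals = [
                dfa_exponent(e[c], scales, mode="nonoverlap", integrate=True)[0]
                for e in eps
            ]
            out[c] = np.mean(vals)
        return out

    alphas_a = np.stack([subject_alphas(s) for s in epochs_a])
    alphas_b = np.stack([subject_alphas(s) for s in epochs_b])
    if alphas_a.shape != alphas_b.shape:
        raise ValueError("class stacks must be paired by subject")
    if alphas_a.shape[0] < 3:
        raise ValueError("need at least 3 subjects for a paired contrast")
    n_ch = alphas_a.shape[1]
    names = ch_names if ch_names is not None else [f"ch{i}" for i in range(n_ch)]
    rows = []
    for c in range(n_ch):
        test, p = _paired_test(alphas_a[:, c], alphas_b[:, c], alpha)
        rows.append(
            {
                "channel": names[c],
                "alpha_a": float(alphas_a[:, c].mean()),
                "alpha_b": float(alphas_b[:, c].mean()),
                "test": test,
                "p": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)
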