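"""Online trial protocol, decoding metrics and group-level statistics.

The online protocol accumulates classifier evidence with an exponential
smoother ``p <- (1 - alpha) p + alpha p_inst`` (alpha = 0.05), updated every
62.5 ms from 0.5, and delivers a command the first time the accumulated
probability surpasses a per-class threshold; a trial with no crossing within
7 s times out, recording the final bar direction.

Sample-wise performance is summarised by accuracy and Cohen's kappa;
command-level performance by completed-trial accuracy (Acc_comp), accuracy
counting timeouts by final bar direction (Acc_approx), and kappa normalised
by the non-timeout fraction, ``kappa_norm = kappa * (1 - n_timeouts /
n_total)``.  Chance levels follow the inverse-binomial-CDF construction at
p = 0.001.  Group contrasts use Friedman's test with Wilcoxon signed-rank
post-hocs, Benjamini-Hochberg FDR adjustment, and Lilliefors normality
screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors
from statsmodels.stats.multitest import multipletests

from .riemann import MDM, AdaptiveReference, rebias

__all__ = [
    "TrialProtocol",
    "TrialOutcome",
    "evidence_update",
    "run_trial",
    "pseudo_online_replay",
    "accuracy",
    "cohen_kappa",
    "kappa_band",
    "chance_level",
    "bar_dynamics",
    "command_metrics",
    "group_stats",
]

LANDIS_KOCH_BANDS = [
    (0.0, "random"),
    (0.2, "poor"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "perfect"),
]


def kappa_band(kappa: float) -> str:
    """Landis & Koch qualitative band for a kappa value."""
    for upper, name in LANDIS_KOCH_BANDS:
        if kappa <= upper:
            return name
    return "perfect"


@dataclass(frozen=True)
class TrialProtocol:
    """Evidence-accumulation protocol configuration.

    ``threshold_per_class`` maps each class to its delivery threshold in
    (0.5, 1]; thresholds were experimenter-set per run in practice and are
    plain configuration here (sample-wise and normalised command metrics do
    not depend on them).
    """

    classes: tuple = ("left", "right")
    threshold_per_class: dict = field(
        default_factory=lambda: {"left": 0.7, "right": 0.7}
    )
    timeout_s: float = 7.0
    update_period_s: float = 0.0625
    alpha: float = 0.05
    initial_probability: float = 0.5

    def __post_init__(self) -> None:
        if len(self.classes) != 2:
            raise ValueError("trial protocol is two-class")
        for cls in self.classes:
            thr = self.threshold_per_class.get(cls)
            if thr is None or not 0.5 < thr <= 1.0:
                raise ValueError(f"threshold for {cls!r} must be in (0.5, 1]")
        if self.timeout_s <= 0:
            raise ValueError("timeout must be positive")

    @property
    def max_updates(self) -> int:
        return int(round(self.timeout_s / self.update_period_s))


@dataclass
class TrialOutcome:
    """Result of one evidence-accumulated trial."""

    truth: object
    delivered: object            # class label, or None on timeout
    timeout: bool
    evidence: np.ndarray         # accumulated probability of classes[0] per update
    duration_s: float
    timeout_direction: object = None  # bar side at timeout (None if exactly 0.5)
    first_class: object = "left"      # the class whose probability the trace stores

    @property
    def correct(self) -> bool:
        return (not self.timeout) and self.delivered == self.truth


def evidence_update(prev: float, p_inst: float, alpha: float = 0.05) -> float:
    """One exponential-smoothing step of the accumulated probability."""
    if not (0.0 <= prev <= 1.0 and 0.0 <= p_inst <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return (1.0 - alpha) * prev + alpha * p_inst


def run_trial(probability_stream, protocol: TrialProtocol, truth) -> TrialOutcome:
    """Run the threshold/timeout machine over a per-update probability stream.

    ``probability_stream`` yields the instantaneous classifier probability of
    ``protocol.classes[0]`` once per update period.  Evidence starts at 0.5;
    the trial ends at the first strict threshold crossing (evidence above the
    first class's threshold, or below one minus the second's) or at timeout,
    whichever comes first.  A stream exhausted early counts as a timeout at
    the point of exhaustion.
    """
    a, b = protocol.classes
    thr_a = protocol.threshold_per_class[a]
    thr_b = protocol.threshold_per_class[b]
    ev = protocol.initial_probability
    trace = []
    delivered = None
    it = iter(probability_stream)
    for k in range(protocol.max_updates):
        try:
            p = next(it)
        except StopIteration:
            break
        ev = evidence_update(ev, float(p), protocol.alpha)
        trace.append(ev)
        if ev > thr_a:
            delivered = a
            break
        if ev < 1.0 - thr_b:
            delivered = b
            break
    if not trace:
        raise ValueError("empty probability stream")
    duration = len(trace) * protocol.update_period_s
    timeout = delivered is None
    direction = None
    if timeout:
        if trace[-1] > 0.5:
            direction = a
        elif trace[-1] < 0.5:
            direction = b
    return TrialOutcome(
        truth=truth,
        delivered=delivered,
        timeout=timeout,
        evidence=np.asarray(trace),
        duration_s=duration,
        timeout_direction=direction,
        first_class=a,
    )


def pseudo_online_replay(
    features: np.ndarray,
    model: MDM,
    adaptation: str = "none",
    reference: np.ndarray | None = None,
    variant: str = "reset",
):
    """Causally replay a test session of SPD features through a fitted MDM.

    ``adaptation`` selects the recentering scheme applied to each incoming
    matrix before prediction: ``"none"``, ``"rebias"`` (fixed ``reference``),
    or ``"adaptive"`` (adaptive reference starting from ``reference``,
    updated after each prediction so causality holds: removing future epochs
    never changes earlier predictions).

    Returns ``(predictions, probabilities)`` with probabilities ordered as
    ``model.classes_``.
    """
    features = np.asarray(features, dtype=float)
    if adaptation not in ("none", "rebias", "adaptive"):
        raise ValueError(f"unknown adaptation scheme {adaptation!r}")
    if adaptation in ("rebias", "adaptive") and reference is None:
        raise ValueError(f"adaptation {adaptation!r} requires a reference matrix")
    state = AdaptiveReference(reference, variant=variant) if adaptation == "adaptive" else None
    preds, probas = [], []
    for C in features:
        if adaptation == "rebias":
            C = rebias(C, reference)
        elif adaptation == "adaptive":
            C = state.step(C)
        preds.append(model.predict(C[None])[0])
        probas.append(model.predict_proba(C[None])[0])
    return np.asarray(preds), np.asarray(probas)


def _as_table(ct) -> np.ndarray:
    t = np.asarray(ct, dtype=float)
    if t.ndim == 1 and t.size == 4:  # (TP, TN, FP, FN)
        tp, tn, fp, fn = t
        t = np.array([[tp, fn], [fp, tn]])
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("confusion table must be square or a (TP,TN,FP,FN) tuple")
    if np.any(t < 0):
        raise ValueError("confusion counts must be non-negative")
    return t


def accuracy(ct) -> float:
    """Fraction of correct predictions from a confusion table."""
    t = _as_table(ct)
    total = t.sum()
    if total == 0:
        raise ValueError("empty confusion table")
    return float(np.trace(t) / total)


def cohen_kappa(ct) -> float:
    """Cohen's kappa with marginal-product expected agreement."""
    t = _as_table(ct)
    total = t.sum()
    if total == 0:
        raise ValueError("empty confusion table")
    po = np.trace(t) / total
    pe = float((t.sum(axis=1) * t.sum(axis=0)).sum()) / total**2
    if pe >= 1.0:
        raise ZeroDivisionError("degenerate marginals: expected agreement is 1")
    return float((po - pe) / (1.0 - pe))


def chance_level(n_trials: int, n_classes: int = 2, alpha: float = 0.001) -> float:
    """Binomial chance threshold: smallest k*/n with CDF(k*) >= 1 - alpha."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    k_star = int(stats.binom.ppf(1.0 - alpha, n_trials, 1.0 / n_classes))
    return k_star / n_trials


def bar_dynamics(outcomes) -> float:
    """Percentage of update steps whose evidence strictly favours the truth."""
    good = total = 0
    for o in outcomes:
        ev = np.asarray(o.evidence)
        total += ev.size
        # evidence is P(classes[0]); "toward truth" flips for the other class
        toward = ev if o.truth == o.first_class else 1.0 - ev
        good += int((toward > 0.5).sum())
    if total == 0:
        raise ValueError("no active epochs")
    return 100.0 * good / total


@dataclass
class CommandMetrics:
    acc_comp: float | None
    acc_approx: float
    n_timeouts: int
    n_total: int
    kappa: float | None
    kappa_norm: float | None


def command_metrics(outcomes, classes=("left", "right")) -> CommandMetrics:
    """Command-delivery metrics from a set of trial outcomes.

    Kappa is computed on the completed-trial confusion table and normalised
    by the non-timeout fraction.  ``Acc_approx`` counts timeouts by final bar
    direction, with a bar exactly at 0.5 counted as an error.
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("need at least one trial")
    idx = {c: i for i, c in enumerate(classes)}
    table = np.zeros((2, 2))
    n_timeouts = 0
    approx_correct = 0
    for o in outcomes:
        if o.timeout:
            n_timeouts += 1
            if o.timeout_direction == o.truth:
                approx_correct += 1
        else:
            table[idx[o.truth], idx[o.delivered]] += 1
            approx_correct += int(o.delivered == o.truth)
    n_total = len(outcomes)
    acc_approx = approx_correct / n_total
    if table.sum() == 0:
        return CommandMetrics(None, acc_approx, n_timeouts, n_total, None, None)
    kap = cohen_kappa(table)
    return CommandMetrics(
        acc_comp=accuracy(table),
        acc_approx=acc_approx,
        n_timeouts=n_timeouts,
        n_total=n_total,
        kappa=kap,
        kappa_norm=kap * (1.0 - n_timeouts / n_total),
    )


def wilcoxon_signed_rank(a, b=None):
    """Wilcoxon signed-rank p-value (exact for n <= 25 without zeros/ties).

    Raises if every paired difference is zero: there are no signed ranks and
    the test is undefined.
    """
    d = np.asarray(a, dtype=float) if b is None else np.asarray(a) - np.asarray(b)
    if np.all(d == 0):
        raise ValueError("all paired differences are zero; signed-rank test undefined")
    method = "exact" if (d.size <= 25 and not np.any(d == 0)) else "approx"
    return float(stats.wilcoxon(d, method=method)[1])


def group_stats(metric_table: np.ndarray, labels=None, alpha: float = 0.05) -> dict:
    """Friedman main effect with Wilcoxon post-hocs over paired pipelines.

    ``metric_table`` is subjects x pipelines (complete, paired).  Pairwise
    Wilcoxon signed-rank p-values are Benjamini-Hochberg adjusted; a
    Lilliefors normality flag is reported per pipeline column.
    """
    table = np.asarray(metric_table, dtype=float)
    if table.ndim != 2 or table.shape[1] < 3:
        raise ValueError("need a subjects x (>= 3) pipelines table")
    if np.any(~np.isfinite(table)):
        raise ValueError("table must be complete")
    n_pipe = table.shape[1]
    if labels is None:
        labels = [f"pipeline{i}" for i in range(n_pipe)]
    if np.allclose(table, table[:, :1]):
        friedman_stat, friedman_p = 0.0, 1.0
    else:
        friedman_stat, friedman_p = stats.friedmanchisquare(*table.T)
    pairs, pvals = [], []
    for i in range(n_pipe):
        for j in range(i + 1, n_pipe):
            try:
                p = wilcoxon_signed_rank(table[:, i], table[:, j])
            except ValueError:
                p = 1.0  # indistinguishable pipelines carry no evidence
            pairs.append((labels[i], labels[j]))
            pvals.append(p)
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    normality = {}
    for i in range(n_pipe):
        col = table[:, i]
        try:
            _, lp = _lilliefors(col, dist="norm")
            normality[labels[i]] = {"p": float(lp), "normal": bool(lp >= alpha)}
        except (ValueError, ZeroDivisionError):
            normality[labels[i]] = {"p": float("nan"), "normal": False}
    return {
        "friedman_statistic": float(friedman_stat),
        "friedman_p": float(friedman_p),
        "pairwise": [
            {"pair": pr, "p": p, "p_fdr": float(a)}
            for pr, p, a in zip(pairs, pvals, adj)
        ],
        "normality": normality,
    }
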