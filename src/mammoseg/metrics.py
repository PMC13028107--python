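"""Segmentation evaluation: overlap metrics, statistics, panoptic quality.

Overlap metrics are the Dice similarity coefficient
DSC = 2|G∩S| / (|G| + |S|) and the Jaccard index
IoU = |G∩S| / |G∪S|, related by DSC = 2 IoU / (1 + IoU). Two empty
masks score 1.0 on both so perfect negatives are not penalized.

Paired per-image improvements are summarized by mean/SD/median/IQR, a
paired t statistic t = dbar / (s_d / sqrt(n)) with a two-sided Student
p-value, Holm-Bonferroni adjustment over the two metric families, and a
seeded percentile-bootstrap confidence interval for the mean difference
(the normal z-interval is reported alongside).

Instance agreement follows the panoptic-quality convention: predicted
and ground-truth instances are matched at IoU > 0.5 (provably unique at
that threshold), SQ is the mean IoU over matched pairs, RQ the F-style
detection score |TP| / (|TP| + |FP|/2 + |FN|/2), and PQ = SQ * RQ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "MetricReport",
    "dice",
    "iou",
    "summarize",
    "paired_t",
    "holm_bonferroni",
    "holm_bonferroni_printed",
    "bootstrap_ci",
    "match_instances",
    "panoptic_quality",
]


@dataclass
class MetricReport:
    """Per-image rows plus aggregate statistics of an evaluation run."""

    per_image: list[dict] = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)
    panoptic: dict = field(default_factory=dict)

    CSV_COLUMNS = (
        "image_id",
        "dsc_initial",
        "dsc_refined",
        "delta_dsc",
        "iou_initial",
        "iou_refined",
        "delta_iou",
    )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.per_image, columns=list(self.CSV_COLUMNS))

    def save(self, csv_path, json_path) -> None:
        """Write per-image rows as CSV and aggregates/tests/CIs as JSON."""
        import json

        self.to_frame().to_csv(csv_path, index=False)
        payload = {
            "aggregate": self.aggregate,
            "tests": self.tests,
            "ci": self.ci,
            "panoptic": self.panoptic,
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _counts(G, S) -> tuple[int, int, int]:
    G = np.asarray(G) > 0
    S = np.asarray(S) > 0
    if G.shape != S.shape:
        raise ValueError(f"shape mismatch: {G.shape} vs {S.shape}")
    inter = int(np.logical_and(G, S).sum())
    return inter, int(G.sum()), int(S.sum())


def dice(G, S) -> float:
    """Dice similarity coefficient 2|G∩S| / (|G| + |S|); empty/empty -> 1."""
    inter, g, s = _counts(G, S)
    if g + s == 0:
        log.debug("dice: both masks empty, scoring 1.0")
        return 1.0
    return 2.0 * inter / (g + s)


def iou(G, S) -> float:
    """Jaccard index |G∩S| / (|G| + |S| - |G∩S|); empty/empty -> 1."""
    inter, g, s = _counts(G, S)
    union = g + s - inter
    if union == 0:
        log.debug("iou: both masks empty, scoring 1.0")
        return 1.0
    return inter / union


def summarize(values) -> dict:
    """Mean, SD (ddof=1 when n>1), median, Q1, Q3, IQR of a sample.

    Quartiles use linear interpolation between order statistics.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sequence")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return {
        "mean": float(v.mean()),
        "sd": sd,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(q3 - q1),
        "n": int(v.size),
    }


def paired_t(before, after) -> tuple[float, float]:
    """Paired t test on d = before - after; two-sided Student p, n-1 df."""
    b = np.asarray(before, dtype=np.float64)
    a = np.asarray(after, dtype=np.float64)
    if b.shape != a.shape or b.ndim != 1:
        raise ValueError("before/after must be equal-length 1-D sequences")
    n = b.size
    if n < 2:
        raise ValueError("paired t needs n >= 2")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate differences: zero variance")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return t, p


def holm_bonferroni(p_dsc: float, p_iou: float) -> tuple[float, float]:
    """Holm step-down adjustment for the two-metric family (m = 2).

    The smaller p-value is doubled; the larger becomes
    max(2 * p_small, p_large); both capped at 1.
    """
    for p in (p_dsc, p_iou):
        if not 0 <= p <= 1:
            raise ValueError(f"p-value out of range: {p}")
    ps = [("dsc", p_dsc), ("iou", p_iou)]
    ps.sort(key=lambda kv: kv[1])
    adj = {ps[0][0]: min(1.0, 2.0 * ps[0][1])}
    adj[ps[1][0]] = min(1.0, max(2.0 * ps[0][1], ps[1][1]))
    return adj["dsc"], adj["iou"]


def holm_bonferroni_printed(p_dsc: float, p_iou: float) -> tuple[float, float]:
    """The literal symmetric-max variant, exposed for comparison only."""
    return (
        min(1.0, max(2.0 * p_dsc, p_iou)),
        min(1.0, max(2.0 * p_iou, p_dsc)),
    )


def bootstrap_ci(
    deltas, n_boot: int = 10000, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Percentile bootstrap CI for the mean of paired differences.

    Returns the percentile interval under ``n_boot`` seeded resamples
    together with the normal-approximation z-interval
    mean ± z_{alpha/2} * s / sqrt(n) for comparison.
    """
    d = np.asarray(deltas, dtype=np.float64)
    if d.size < 2:
        raise ValueError("bootstrap needs n >= 2")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    means = d[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    z = stats.norm.ppf(1 - alpha / 2)
    se = d.std(ddof=1) / np.sqrt(d.size)
    return {
        "low": float(lo),
        "high": float(hi),
        "z_low": float(d.mean() - z * se),
        "z_high": float(d.mean() + z * se),
    }


def _instance_iou_table(pred, truth):
    pred = np.asarray(pred).astype(np.int64)
    truth = np.asarray(truth).astype(np.int64)
    if pred.shape != truth.shape:
        raise ValueError("label maps must share a shape")
    p_ids = np.unique(pred[pred > 0])
    t_ids = np.unique(truth[truth > 0])
    p_areas = {int(i): int((pred == i).sum()) for i in p_ids}
    t_areas = {int(i): int((truth == i).sum()) for i in t_ids}
    both = (pred > 0) & (truth > 0)
    pairs, counts = np.unique(
        np.stack([pred[both], truth[both]]), axis=1, return_counts=True
    )
    table = {}
    for (pi, ti), inter in zip(pairs.T.tolist(), counts.tolist()):
        table[(int(pi), int(ti))] = inter / (p_areas[int(pi)] + t_areas[int(ti)] - inter)
    return table, p_ids.tolist(), t_ids.tolist()


def match_instances(pred, truth, iou_threshold: float = 0.5):
    """Match predicted and ground-truth instances by IoU.

    Pairs with IoU strictly greater than the threshold are true
    positives (unique at threshold 0.5; below that, greedy matching by
    descending IoU with lowest-id tie-break). Returns
    ``(tp_pairs, fp_ids, fn_ids)`` where ``tp_pairs`` is a list of
    ``(pred_id, truth_id, iou)``.
    """
    table, p_ids, t_ids = _instance_iou_table(pred, truth)
    cands = sorted(table.items(), key=lambda kv: (-kv[1], kv[0]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = []
    for (pi, ti), v in cands:
        if v > iou_threshold and pi not in used_p and ti not in used_t:
            tp.append((pi, ti, v))
            used_p.add(pi)
            used_t.add(ti)
    fp = [i for i in p_ids if i not in used_p]
    fn = [i for i in t_ids if i not in used_t]
    return tp, fp, fn


def panoptic_quality(pred, truth, iou_threshold: float = 0.5):
    """SQ, RQ, PQ from the matched instances.

    SQ is the mean IoU over matches, RQ = |TP| / (|TP| + |FP|/2 +
    |FN|/2), and PQ = SQ * RQ; all three are 0 when there is no match.
    """
    tp, fp, fn = match_instances(pred, truth, iou_threshold)
    if not tp:
        return 0.0, 0.0, 0.0
    sq = float(np.mean([v for _, _, v in tp]))
    rq = len(tp) / (len(tp) + 0.5 * len(fp) + 0.5 * len(fn))
    return sq, rq, sq * rq
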