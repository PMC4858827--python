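"""Statistical comparison of modality-specific models against the reference.

The rotational-angiography model (DM) is the reference ("standard model").
For each parameter the per-patient difference is Δ% = |test − ref| / ref ×
100; cohorts are summarized as mean ± SE (SE = sample SD / √n) with a paired
two-sided Wilcoxon signed-rank test on the raw paired values.  Categorical
flow characteristics (flow pattern, impingement size, jet size) are compared
with unweighted Cohen's kappa, categorized as poor (κ ≤ 0.4), moderate
(0.4 < κ ≤ 0.75) or good (κ > 0.75).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import AneumorphError


# --------------------------------------------------------------------------
# elementary statistics
# --------------------------------------------------------------------------

def percent_difference(test_value: float, reference_value: float) -> float:
    """Δ% = |test − ref| / ref × 100; NaN when the reference is zero."""
    if reference_value == 0 or not math.isfinite(reference_value):
        return float("nan")
    return abs(test_value - reference_value) / abs(reference_value) * 100.0


@dataclass
class WilcoxonResult:
    p_value: float
    statistic: float      # W+ (sum of positive-difference ranks)
    n: int                # pairs after zero-difference removal
    degenerate: bool = False
    method: str = "exact"

    def __float__(self):
        return self.p_value


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic with mid-ranks.

    Doubling mid-ranks makes them integers; the null distribution of the
    doubled statistic is built by dynamic programming over sign assignments.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        nxt = pmf.copy()
        nxt[r:] += pmf[: total + 1 - r]
        pmf = nxt / 2.0
    w2 = int(round(2 * w_plus))
    cdf = pmf[: w2 + 1].sum()
    sf = pmf[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def paired_wilcoxon(x: Sequence[float], y: Sequence[float],
                    exact_max_n: int = 25) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; ties are mid-ranked.  The null
    distribution is exact (sign-assignment enumeration via DP) for
    n ≤ ``exact_max_n``, and a normal approximation with tie correction
    above.  All-zero differences yield p = 1 with a degeneracy flag.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise AneumorphError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(p_value=1.0, statistic=0.0, n=0,
                              degenerate=True, method="degenerate")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(p_value=p, statistic=w_plus, n=n, method="exact")
    mean = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((counts ** 3 - counts).sum()) / 48.0
    if var <= 0:
        return WilcoxonResult(p_value=1.0, statistic=w_plus, n=n,
                              degenerate=True, method="normal")
    from scipy.stats import norm

    z = (w_plus - mean) / math.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(p_value=p, statistic=w_plus, n=n, method="normal")


_KAPPA_CATEGORIES = ((0.75, "good"), (0.4, "moderate"))


def agreement_category(kappa: float) -> str:
    """Agreement category with boundary values assigned to the lower class."""
    for cut, name in _KAPPA_CATEGORIES:
        if kappa > cut:
            return name
    return "poor"


def cohen_kappa(labels_a: Sequence, labels_b: Sequence):
    """Unweighted Cohen's kappa and its agreement category.

    κ = (p_o − p_e) / (1 − p_e).  Boundary values fall into the lower
    category: poor (κ ≤ 0.4), moderate (0.4 < κ ≤ 0.75), good (κ > 0.75).
    Two identical constant raters (p_e = 1) define κ = 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise AneumorphError("label vectors must be equal-length and nonempty")
    cats = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-12:
        kappa = 1.0 if p_o >= 1.0 - 1e-12 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return float(kappa), agreement_category(kappa)


# --------------------------------------------------------------------------
# cohort summaries
# --------------------------------------------------------------------------

@dataclass
class ModelTriplet:
    """All per-modality reports of one (synthetic) patient.

    ``reports`` maps modality ("DM", "CM", "MM") to a flat dict of
    parameter → value; ``flow_labels`` optionally maps modality to a dict of
    categorical flow characteristics (e.g. FP / IS / JS).
    """

    patient_id: str
    reports: Dict[str, Dict[str, float]]
    flow_labels: Optional[Dict[str, Dict[str, str]]] = None
    distances: Optional[Dict[str, Dict[str, float]]] = None   # modality -> stats vs DM
    config_hash: Optional[str] = None


def triplets_to_long(triplets: Sequence[ModelTriplet]) -> pd.DataFrame:
    rows = []
    for t in triplets:
        for modality, report in t.reports.items():
            for parameter, value in report.items():
                rows.append({"patient_id": t.patient_id, "modality": modality,
                             "parameter": parameter, "value": value})
    return pd.DataFrame(rows)


def summarize_cohort(triplets: Sequence[ModelTriplet], reference: str = "DM",
                     parameters: Optional[Sequence[str]] = None):
    """Cohort comparison tables against the reference modality.

    Returns a dict with:

    * ``summary`` — per parameter and comparison: mean Δ%, SE, Wilcoxon p, n;
    * ``deltas`` — long-format per-patient Δ% (boxplot-ready);
    * ``kappa`` — agreement table for categorical flow labels (or None);
    * ``notes`` — excluded patients / undefined references.
    """
    if len(triplets) < 2:
        raise AneumorphError("cohort summary needs n >= 2 patients")
    hashes = {t.config_hash for t in triplets if t.config_hash is not None}
    if len(hashes) > 1:
        raise AneumorphError(
            "refusing to mix outputs from different study configs: "
            f"{sorted(hashes)}")

    notes = []
    modalities = sorted({m for t in triplets for m in t.reports} - {reference})
    if parameters is None:
        parameters = []
        for t in triplets:
            for rep in t.reports.values():
                for p in rep:
                    if p not in parameters:
                        parameters.append(p)

    delta_rows, summary_rows = [], []
    for modality in modalities:
        for parameter in parameters:
            ref_vals, test_vals, deltas = [], [], []
            for t in triplets:
                if reference not in t.reports or modality not in t.reports:
                    notes.append(f"{t.patient_id}: missing {modality} or "
                                 f"{reference}; excluded from {modality} comparison")
                    continue
                r = t.reports[reference].get(parameter)
                v = t.reports[modality].get(parameter)
                if r is None or v is None or not np.isfinite([r, v]).all():
                    notes.append(f"{t.patient_id}/{parameter}: undefined value; excluded")
                    continue
                dp = percent_difference(v, r)
                if not math.isfinite(dp):
                    notes.append(f"{t.patient_id}/{parameter}: reference is zero; excluded")
                    continue
                ref_vals.append(r)
                test_vals.append(v)
                deltas.append(dp)
                delta_rows.append({"patient_id": t.patient_id, "parameter": parameter,
                                   "comparison": f"{modality} vs {reference}",
                                   "delta_pct": dp})
            if not deltas:
                continue
            deltas = np.array(deltas)
            n = len(deltas)
            se = float(deltas.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
            wres = paired_wilcoxon(test_vals, ref_vals)
            summary_rows.append({
                "parameter": parameter, "comparison": f"{modality} vs {reference}",
                "n": n, "mean_delta_pct": float(deltas.mean()), "se_delta_pct": se,
                "wilcoxon_p": wres.p_value, "significant": wres.p_value <= 0.05,
            })

    distance_df = None
    if any(t.distances for t in triplets):
        drows = []
        for modality in modalities:
            vals = [t.distances[modality]["mean"] for t in triplets
                    if t.distances and modality in t.distances]
            maxs = [t.distances[modality]["max"] for t in triplets
                    if t.distances and modality in t.distances]
            if vals:
                drows.append({
                    "comparison": f"{modality} vs {reference}", "n": len(vals),
                    "mean_mm": float(np.mean(vals)),
                    "sd_mm": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                    "max_mm": float(np.max(maxs)),
                })
        distance_df = pd.DataFrame(drows)

    kappa_df = None
    if any(t.flow_labels for t in triplets):
        krows = []
        characteristics = sorted({c for t in triplets if t.flow_labels
                                  for lab in t.flow_labels.values() for c in lab})
        for modality in modalities:
            for char in characteristics:
                pairs = [(t.flow_labels[reference][char], t.flow_labels[modality][char])
                         for t in triplets
                         if t.flow_labels and reference in t.flow_labels
                         and modality in t.flow_labels
                         and char in t.flow_labels[reference]
                         and char in t.flow_labels[modality]]
                if not pairs:
                    continue
                ka, kb = zip(*pairs)
                kappa, cat = cohen_kappa(list(ka), list(kb))
                krows.append({"characteristic": char,
                              "comparison": f"{modality} vs {reference}",
                              "kappa": kappa, "agreement": cat, "n": len(pairs)})
        kappa_df = pd.DataFrame(krows)

    return {
        "summary": pd.DataFrame(summary_rows),
        "deltas": pd.DataFrame(delta_rows),
        "surface_distance": distance_df,
        "kappa": kappa_df,
        "notes": notes,
    }
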