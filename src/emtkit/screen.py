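"""High-content screen quantification.

Takes per-cell plate tables (one row per segmented cell with vimentin and
phospho-ERK intensities) through the screen-analysis chain:

1. train a depth-2 axis-aligned decision tree separating cells of
   unstimulated-like (positive-control) wells from stimulated-vehicle
   (negative-control) wells on mean and total vimentin intensity;
2. summarize wells (cell count, percent vimentin-positive, mean pERK);
3. control-normalize with percent inhibition
   ``100*(1 - (x - mean(x_pos)) / (mean(x_neg) - mean(x_pos)))``;
4. fit a four-parameter logistic (4PL) of percent inhibition versus
   log10(dose) and report the absolute 50%-inhibition crossing as the IC50,
   censored to the tested dose range (``">MAX"`` / ``"<MIN"`` tokens).

Well roles follow screening convention: a positive control is a
full-effect reference (e.g. 1 uM erlotinib), a negative control the
uninhibited vehicle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import InputError, NumericalError

__all__ = [
    "logistic4",
    "VimClassifier",
    "train_vim_classifier",
    "summarize_wells",
    "percent_inhibition",
    "DoseResponseResult",
    "fit_dose_response",
    "extract_ic50",
    "quantify_plate",
    "READOUTS",
]

CLASSIFIER_FEATURES = ("vim_mean", "vim_total")
READOUTS = ("pct_vim_pos", "cell_count", "perk")
MAX_THRESHOLD_CANDIDATES = 512


# ---------------------------------------------------------------------------
# Four-parameter logistic
# ---------------------------------------------------------------------------

def logistic4(dose, bottom, top, hill, midpoint):
    """4PL response at ``dose`` (uM): bottom + (top-bottom)/(1+10^((log10 m - log10 d)*hill)).

    With ``hill > 0`` the curve rises from ``bottom`` (dose -> 0) to ``top``
    (dose -> inf), the parameterization used for percent inhibition.
    """
    dose = np.asarray(dose, dtype=float)
    logd = np.log10(dose)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((math.log10(midpoint) - logd) * hill))


# ---------------------------------------------------------------------------
# Vimentin classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Split:
    feature: str
    threshold: float
    # children are either a bool leaf (True = vimentin-positive) or a _Split
    left: "bool | _Split"
    right: "bool | _Split"

    def n_nodes(self) -> int:
        n = 1
        for child in (self.left, self.right):
            if isinstance(child, _Split):
                n += child.n_nodes()
        return n

    def predict(self, features: Mapping[str, np.ndarray]) -> np.ndarray:
        x = np.asarray(features[self.feature], dtype=float)
        out = np.empty(x.shape, dtype=bool)
        mask = x <= self.threshold
        for child, m in ((self.left, mask), (self.right, ~mask)):
            if isinstance(child, _Split):
                out[m] = child.predict({f: np.asarray(features[f])[m]
                                        for f in CLASSIFIER_FEATURES})
            else:
                out[m] = child
        return out

    def to_dict(self) -> dict:
        def enc(child):
            return child.to_dict() if isinstance(child, _Split) else bool(child)
        return {"feature": self.feature, "threshold": self.threshold,
                "left": enc(self.left), "right": enc(self.right)}

    @staticmethod
    def from_dict(d: dict) -> "_Split":
        def dec(child):
            return _Split.from_dict(child) if isinstance(child, dict) else bool(child)
        return _Split(d["feature"], float(d["threshold"]),
                      dec(d["left"]), dec(d["right"]))


@dataclass
class VimClassifier:
    """Depth-<=2 axis-aligned decision rule over (vim_mean, vim_total).

    ``training_score`` is the balanced accuracy separating positive-control
    from negative-control cells at training time.  The rule serializes to
    JSON and reloads with bit-identical predictions.
    """

    tree: _Split
    training_score: float

    @property
    def primary_feature(self) -> str:
        return self.tree.feature

    @property
    def primary_threshold(self) -> float:
        return self.tree.threshold

    def predict(self, cells: pd.DataFrame) -> np.ndarray:
        """Boolean vimentin-positive call per row of a per-cell table."""
        return self.tree.predict({f: cells[f].to_numpy(dtype=float)
                                  for f in CLASSIFIER_FEATURES})

    def to_json(self) -> str:
        return json.dumps({"tree": self.tree.to_dict(),
                           "training_score": self.training_score})

    @classmethod
    def from_json(cls, text: str) -> "VimClassifier":
        d = json.loads(text)
        return cls(tree=_Split.from_dict(d["tree"]),
                   training_score=float(d["training_score"]))


def _candidate_thresholds(values: np.ndarray,
                          max_candidates: int = MAX_THRESHOLD_CANDIDATES
                          ) -> np.ndarray:
    """Midpoints of consecutive sorted unique values, evenly subsampled."""
    uniq = np.unique(values)
    if uniq.size < 2:
        return np.empty(0)
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    if mids.size > max_candidates:
        idx = np.linspace(0, mids.size - 1, max_candidates).round().astype(int)
        mids = mids[np.unique(idx)]
    return mids


def _best_leaf_or_split(side_mask: np.ndarray, w_pos: np.ndarray,
                        w_neg: np.ndarray, sort_orders: dict,
                        candidates: dict, min_leaf_weight: float,
                        min_gain: float):
    """Best refinement of one child region: a leaf, or one further split.

    Returns (error, child) where ``child`` is a bool leaf or a _Split whose
    own children are leaves.  Splits isolating less than ``min_leaf_weight``
    of class-balanced weight on either side are not considered (overfitting
    guard).  Ties prefer the leaf, then the lower threshold, then the
    lexicographically first feature.
    """
    tot_pos = float(w_pos[side_mask].sum())
    tot_neg = float(w_neg[side_mask].sum())
    leaf_label = tot_pos >= tot_neg
    best = (min(tot_pos, tot_neg), 0, 0.0, "", leaf_label)  # err, nodes, thr, feat, child
    for feat in CLASSIFIER_FEATURES:
        order, sorted_vals = sort_orders[feat]
        thr = candidates[feat]
        if thr.size == 0:
            continue
        m = side_mask[order]
        vals = sorted_vals[m]
        cpos = np.concatenate([[0.0], np.cumsum(w_pos[order][m])])
        cneg = np.concatenate([[0.0], np.cumsum(w_neg[order][m])])
        idx = np.searchsorted(vals, thr, side="right")
        lpos, lneg = cpos[idx], cneg[idx]
        rpos, rneg = tot_pos - lpos, tot_neg - lneg
        err = np.minimum(lpos, lneg) + np.minimum(rpos, rneg)
        small = np.minimum(lpos + lneg, rpos + rneg) < min_leaf_weight
        err = np.where(small, np.inf, err)
        k = int(np.lexsort((thr, err))[0])  # min error, then lowest threshold
        if err[k] < best[0] - max(min_gain, 1e-12):
            split = _Split(feat, float(thr[k]),
                           bool(lpos[k] >= lneg[k]), bool(rpos[k] >= rneg[k]))
            best = (float(err[k]), 2, float(thr[k]), feat, split)
    return best[0], best[4]


def train_vim_classifier(control_cells: pd.DataFrame,
                         min_cells_per_class: int = 50,
                         max_candidates: int = MAX_THRESHOLD_CANDIDATES,
                         min_leaf_weight: float = 0.15,
                         min_split_gain: float = 0.02) -> VimClassifier:
    """Fit the vimentin+/- rule from a plate's control wells.

    Cells from negative-control wells (stimulated vehicle, mesenchymal-
    shifted) are the vimentin-positive-enriched class; cells from
    positive-control wells (full-effect reference, epithelial-like) the
    negative class.  The depth-2 tree minimizing class-balanced
    misclassification of well provenance is found by exhaustive search over
    candidate thresholds (midpoints of consecutive sorted unique feature
    values, subsampled to at most ``max_candidates`` per feature).  Two
    regularizers keep noise slivers between the control populations from
    inflating the positive call rate: splits leaving less than
    ``min_leaf_weight`` of the class-balanced weight (out of 2.0 total) in
    a leaf are rejected, and a child split must improve the weighted error
    by more than ``min_split_gain`` over the plain leaf.  Ties are broken
    by fewer nodes, then the lower first threshold, then feature name.
    """
    roles = control_cells["role"].to_numpy()
    y = roles == "neg_ctrl"
    n_pos_class, n_neg_class = int(y.sum()), int((~y).sum())
    if n_pos_class < min_cells_per_class or n_neg_class < min_cells_per_class:
        raise InputError(
            f"need >={min_cells_per_class} cells per control class, got "
            f"neg_ctrl={n_pos_class}, pos_ctrl={n_neg_class}")
    # balance the two provenance classes
    w_pos = np.where(y, 1.0 / n_pos_class, 0.0)
    w_neg = np.where(y, 0.0, 1.0 / n_neg_class)

    feats = {f: control_cells[f].to_numpy(dtype=float)
             for f in CLASSIFIER_FEATURES}
    sort_orders = {}
    candidates = {}
    for f, x in feats.items():
        order = np.argsort(x, kind="stable")
        sort_orders[f] = (order, x[order])
        candidates[f] = _candidate_thresholds(x, max_candidates)
    if all(c.size == 0 for c in candidates.values()):
        raise NumericalError("control-cell features are constant; cannot "
                             "train a classifier")

    def better(key, ref):
        # strict error improvement wins; near-ties fall back to
        # (fewer nodes, lower first threshold, feature name)
        if key[0] < ref[0] - 1e-12:
            return True
        if key[0] > ref[0] + 1e-12:
            return False
        return key[1:] < ref[1:]

    best_key, best_tree = None, None
    for enforce_min_leaf in (True, False):
        wmin = min_leaf_weight if enforce_min_leaf else 0.0
        for root_feat in CLASSIFIER_FEATURES:
            x = feats[root_feat]
            for thr in candidates[root_feat]:
                left = x <= thr
                lw = w_pos[left].sum() + w_neg[left].sum()
                if min(lw, 2.0 - lw) < wmin:
                    continue
                err_l, child_l = _best_leaf_or_split(left, w_pos, w_neg,
                                                     sort_orders, candidates,
                                                     wmin, min_split_gain)
                err_r, child_r = _best_leaf_or_split(~left, w_pos, w_neg,
                                                     sort_orders, candidates,
                                                     wmin, min_split_gain)
                tree = _Split(root_feat, float(thr), child_l, child_r)
                key = (err_l + err_r, tree.n_nodes(), float(thr), root_feat)
                if best_key is None or better(key, best_key):
                    best_key, best_tree = key, tree
        if best_key is not None:
            break  # only relax the leaf-weight floor if nothing qualified
    error = max(0.0, best_key[0])
    return VimClassifier(tree=best_tree, training_score=1.0 - error / 2.0)


# ---------------------------------------------------------------------------
# Well summaries and percent inhibition
# ---------------------------------------------------------------------------

def summarize_wells(cells: pd.DataFrame, wells: pd.DataFrame,
                    classifier: VimClassifier) -> pd.DataFrame:
    """Per-well cell count, percent vimentin-positive and mean pERK.

    Every non-empty well in the metadata appears in the output; wells with
    zero imaged cells carry NaN percentages and ``flag="no_cells"``.
    """
    cells = cells.copy()
    cells["_vim_pos"] = classifier.predict(cells)
    grouped = cells.groupby("well", sort=True).agg(
        n_cells=("cell_id", "size"),
        n_vim_pos=("_vim_pos", "sum"),
        mean_perk=("perk_mean", "mean"),
    )
    meta_cols = ["well", "role", "compound", "dose_uM", "stimulus"]
    out = wells.loc[wells["role"] != "empty", meta_cols].copy()
    out = out.merge(grouped, on="well", how="left")
    out["n_cells"] = out["n_cells"].fillna(0).astype(int)
    out["pct_vim_pos"] = np.where(
        out["n_cells"] > 0, 100.0 * out["n_vim_pos"] / out["n_cells"], np.nan)
    out["flag"] = np.where(out["n_cells"] == 0, "no_cells", "")
    return out.drop(columns=["n_vim_pos"]).sort_values("well").reset_index(drop=True)


def percent_inhibition(x, x_pos_wells, x_neg_wells):
    """Control-normalized response: 100*(1-(x-mean(x_pos))/(mean(x_neg)-mean(x_pos))).

    ``x_pos_wells`` / ``x_neg_wells`` are the well-level values of the
    measured variable over positive and negative control wells.  The result
    is not clipped: responses beyond the controls land outside [0, 100].
    """
    x = np.asarray(x, dtype=float)
    mean_pos = float(np.nanmean(np.asarray(x_pos_wells, dtype=float)))
    mean_neg = float(np.nanmean(np.asarray(x_neg_wells, dtype=float)))
    if not np.isfinite(mean_pos) or not np.isfinite(mean_neg) \
            or mean_neg == mean_pos:
        raise NumericalError(
            f"degenerate controls: mean(x_neg)={mean_neg!r} equals "
            f"mean(x_pos)={mean_pos!r}")
    return 100.0 * (1.0 - (x - mean_pos) / (mean_neg - mean_pos))


# ---------------------------------------------------------------------------
# Dose-response fitting
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseResult:
    """A fitted 4PL inhibition curve with a censorable IC50 (one Table cell).

    ``midpoint`` is the curve inflection (uM); ``ic50`` the absolute
    50%-inhibition crossing, or a censor token when it falls outside the
    tested range.  After canonicalization ``hill > 0`` and ``top`` is the
    high-inhibition plateau.
    """

    compound: str = ""
    condition: str = ""
    readout: str = ""
    bottom: float = math.nan
    top: float = math.nan
    hill: float = math.nan
    midpoint: float = math.nan
    ic50: "float | str" = math.nan
    residual_norm: float = math.nan
    converged: bool = False
    n_points: int = 0
    note: str = ""


def _fit_starts(logd: np.ndarray, resp: np.ndarray):
    lo, hi = float(np.min(resp)), float(np.max(resp))
    half = 0.5 * (lo + hi)
    above = logd[resp >= half]
    mids = [float(np.median(logd))]
    if above.size and above.size < resp.size:
        mids.append(float(np.min(above)))
    for mid in mids:
        for hill in (0.5, 1.0, 2.0):
            yield (lo, hi, hill, mid)


def fit_dose_response(doses: Sequence[float], responses: Sequence[float],
                      compound: str = "", condition: str = "",
                      readout: str = "") -> DoseResponseResult:
    """Least-squares 4PL fit of response (percent inhibition) vs log10 dose.

    Deterministic multi-start initialization: plateaus from the response
    extremes, midpoint from the dose first reaching the half-range and the
    median dose, hill over a small grid.  Degenerate inputs (constant
    response) come back flagged unconverged rather than with a spurious
    curve.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    ok = np.isfinite(d) & np.isfinite(r) & (d > 0)
    d, r = d[ok], r[ok]
    result = DoseResponseResult(compound=compound, condition=condition,
                                readout=readout, n_points=int(d.size))
    if np.unique(d).size < 4:
        raise InputError("need >=4 distinct positive doses for a 4PL fit")
    if np.ptp(r) < 1e-9:
        result.note = "degenerate: constant responses"
        return result
    logd = np.log10(d)

    def model(ld, bottom, top, hill, logmid):
        return bottom + (top - bottom) / (1.0 + 10.0 ** ((logmid - ld) * hill))

    span = np.ptp(r)
    best = None
    for bottom0, top0, hill0, mid0 in _fit_starts(logd, r):
        try:
            popt, _ = curve_fit(
                model, logd, r, p0=(bottom0, top0, hill0, mid0),
                bounds=([np.min(r) - 2 * span, np.min(r) - 2 * span, -20.0,
                         logd.min() - 3], [np.max(r) + 2 * span,
                                           np.max(r) + 2 * span, 20.0,
                                           logd.max() + 3]),
                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((model(logd, *popt) - r) ** 2))
        if best is None or ssr < best[0] - 1e-12:
            best = (ssr, popt)
    if best is None:
        result.note = "non-convergence from all starts"
        return result
    ssr, (bottom, top, hill, logmid) = best
    if hill < 0:  # canonicalize: top is the high-inhibition plateau
        bottom, top, hill = top, bottom, -hill
    if abs(hill) < 1e-8 or abs(top - bottom) < 1e-9:
        result.note = "degenerate: flat fitted curve"
        return result
    result.bottom, result.top = float(bottom), float(top)
    result.hill, result.midpoint = float(hill), float(10.0 ** logmid)
    result.residual_norm = math.sqrt(ssr)
    result.converged = True
    return result


def extract_ic50(fit: DoseResponseResult,
                 tested_range: tuple[float, float]) -> "float | str":
    """Absolute 50%-inhibition crossing of the fitted curve, range-censored.

    Solves fitted response = 50 (not the curve inflection).  If the curve
    never reaches 50 within the tested doses, or crosses outside
    ``tested_range = (MIN, MAX)``, the screening-report censor token
    ``">MAX"`` or ``"<MIN"`` is returned, formatted with the plate's actual
    bounds.
    """
    lo, hi = float(tested_range[0]), float(tested_range[1])
    if not (0 < lo < hi):
        raise InputError(f"invalid tested range {tested_range!r}")
    if not fit.converged:
        return f">{hi:g}"
    b, t, h, m = fit.bottom, fit.top, fit.hill, fit.midpoint
    if t <= 50.0:  # plateau never reaches half-inhibition
        return f">{hi:g}"
    if b >= 50.0:  # above half-inhibition already at dose -> 0
        return f"<{lo:g}"
    d50 = 10.0 ** (math.log10(m) - math.log10((t - 50.0) / (50.0 - b)) / h)
    if d50 > hi:
        return f">{hi:g}"
    if d50 < lo:
        return f"<{lo:g}"
    return float(d50)


# ---------------------------------------------------------------------------
# Plate-level convenience pipeline
# ---------------------------------------------------------------------------

_READOUT_COLUMN = {"pct_vim_pos": "pct_vim_pos", "cell_count": "n_cells",
                   "perk": "mean_perk"}


def quantify_plate(cells: pd.DataFrame, wells: pd.DataFrame,
                   classifier: VimClassifier | None = None,
                   readouts: Sequence[str] = ("pct_vim_pos", "cell_count"),
                   ) -> dict:
    """Run classify -> summarize -> inhibit -> fit -> censor on one plate.

    Returns ``{"summaries": DataFrame, "results": {readout: DoseResponseResult},
    "classifier": VimClassifier}``.  If no classifier is given, one is
    trained on this plate's control wells.
    """
    if classifier is None:
        ctrl = cells[cells["role"].isin(("pos_ctrl", "neg_ctrl"))]
        classifier = train_vim_classifier(ctrl)
    summaries = summarize_wells(cells, wells, classifier)
    dose_rows = summaries[summaries["role"] == "dose"]
    if dose_rows.empty:
        raise InputError("plate has no dose wells")
    compound = dose_rows["compound"].iloc[0]
    condition = dose_rows["stimulus"].iloc[0]
    tested = (float(dose_rows["dose_uM"].min()),
              float(dose_rows["dose_uM"].max()))
    pos = summaries[summaries["role"] == "pos_ctrl"]
    neg = summaries[summaries["role"] == "neg_ctrl"]
    results = {}
    for readout in readouts:
        col = _READOUT_COLUMN[readout]
        inhib = percent_inhibition(dose_rows[col].to_numpy(),
                                   pos[col].to_numpy(), neg[col].to_numpy())
        fit = fit_dose_response(dose_rows["dose_uM"].to_numpy(), inhib,
                                compound=compound, condition=condition,
                                readout=readout)
        fit.ic50 = extract_ic50(fit, tested)
        results[readout] = fit
    return {"summaries": summaries, "results": results,
            "classifier": classifier}
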