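"""Baseline/vehicle normalization and edge tracking across sequential
receptor-antagonist treatments.

Antagonists (BIC, then AP-5, then CNQX, each added on top of the previous)
are recorded as a sequence of conditions per well, with vehicle (DMSO)
wells at the matching cumulative concentrations.  Features are expressed
as fold change over baseline, divided by the mean vehicle fold change, to
cancel the DMSO effect.  Network edges (electrode pairs) are categorized
per condition as high synchrony (score >= 0.40), low synchrony (< 0.40)
or inactive (either electrode silent), tracked across conditions, and
normalized to the number of edges active under BIC — the disinhibited
state in which all available excitatory networks are assumed visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import assign_cross_section
from .synchrony import SynchronyMatrix

HIGH_SYNCHRONY_THRESHOLD = 0.40
CHEM_CONDITIONS = ("baseline", "BIC", "AP5+BIC", "CNQX+AP5+BIC")
VEHICLE_MATCH = {
    "baseline": "baseline",
    "BIC": "vehicle_0.037",
    "AP5+BIC": "vehicle_0.10",
    "CNQX+AP5+BIC": "vehicle_0.27",
}
CATEGORIES = ("high", "low", "inactive")


@dataclass
class TreatmentSeries:
    """Synchrony matrices of one treated well across the four conditions.

    ``matrices`` maps each chemical condition to the well's
    :class:`~mea3d.synchrony.SynchronyMatrix`; all conditions must share
    the electrode layout.
    """

    matrices: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CHEM_CONDITIONS if c not in self.matrices]
        if missing:
            raise ValueError(f"missing conditions: {missing}")
        addr0 = self.matrices[CHEM_CONDITIONS[0]].addresses
        for c in CHEM_CONDITIONS[1:]:
            if self.matrices[c].addresses != addr0:
                raise ValueError("all conditions must share one electrode layout")


def vehicle_fold_change(
    chem_value: float,
    chem_baseline_mean: float,
    vehicle_ratios,
) -> float:
    """Treatment effect as fold change over the vehicle response.

    The treated well's feature is first normalized to its own baseline
    (``chem_value / chem_baseline_mean``), then divided by the mean of the
    vehicle wells' baseline-normalized ratios at the matched DMSO step.
    Vehicle wells evaluated against themselves give exactly 1.  A zero
    baseline or zero vehicle ratio makes the fold change undefined; NaN is
    returned with a warning rather than 0.
    """
    vehicle_ratios = np.atleast_1d(np.asarray(vehicle_ratios, dtype=float))
    if chem_baseline_mean <= 0 or not np.all(np.isfinite(vehicle_ratios)):
        warnings.warn("fold change undefined (zero baseline); reporting NaN")
        return float("nan")
    veh = float(vehicle_ratios.mean())
    if veh <= 0:
        warnings.warn("fold change undefined (zero vehicle ratio); reporting NaN")
        return float("nan")
    return (chem_value / chem_baseline_mean) / veh


def feature_fold_changes(
    chem_summaries: dict,
    vehicle_summaries: list,
    feature: str = "firing_rate",
) -> pd.DataFrame:
    """Per-section vehicle-normalized fold changes for each condition.

    ``chem_summaries`` maps chemical conditions to aggregated section
    summaries (see :func:`mea3d.sections.aggregate`); ``vehicle_summaries``
    is one such dict per vehicle well, keyed by vehicle conditions.
    Returns a DataFrame (conditions x sections) of fold changes.
    """
    col = f"{feature}_mean"
    base = chem_summaries["baseline"]
    rows = {}
    for cond in CHEM_CONDITIONS[1:]:
        veh_cond = VEHICLE_MATCH[cond]
        row = {}
        for section in base.index:
            if section == "full":
                continue
            ratios = []
            for veh in vehicle_summaries:
                b = veh["baseline"].loc[section, col]
                ratios.append(veh[veh_cond].loc[section, col] / b if b > 0 else np.nan)
            ratios = [r for r in ratios if np.isfinite(r)]
            row[section] = (
                vehicle_fold_change(
                    chem_summaries[cond].loc[section, col],
                    base.loc[section, col],
                    ratios,
                )
                if ratios
                else float("nan")
            )
        rows[cond] = row
    return pd.DataFrame(rows).T


def classify_edges(
    matrix: SynchronyMatrix,
    threshold: float = HIGH_SYNCHRONY_THRESHOLD,
) -> pd.DataFrame:
    """Categorize every electrode pair of a synchrony matrix.

    high: score >= threshold; low: active but score < threshold;
    inactive: either electrode silent (NaN score).  Returns one row per
    unordered pair with electrode indices, section labels, score and
    category.
    """
    n = len(matrix.addresses)
    secs = matrix.sections
    iu = np.triu_indices(n, k=1)
    scores = matrix.scores[iu]
    cats = np.where(
        np.isnan(scores), "inactive", np.where(scores >= threshold, "high", "low")
    )
    return pd.DataFrame(
        {
            "i": iu[0],
            "j": iu[1],
            "section_i": [secs[k] for k in iu[0]],
            "section_j": [secs[k] for k in iu[1]],
            "within_section": [secs[a] == secs[b] for a, b in zip(*iu)],
            "score": scores,
            "category": cats,
        }
    )


def edge_fractions_wrt_bic(series: TreatmentSeries, threshold: float = HIGH_SYNCHRONY_THRESHOLD) -> pd.DataFrame:
    """Per-condition edge-category counts as fractions of BIC-active edges.

    The denominator is the number of edges active (non-missing) during BIC
    treatment, under the assumption that GABA_A disinhibition reveals all
    available excitatory networks.  Fractions of one condition therefore
    need not sum to 1.
    """
    bic = classify_edges(series.matrices["BIC"], threshold)
    n_bic_active = int((bic["category"] != "inactive").sum())
    if n_bic_active == 0:
        raise ValueError("no active edges under BIC; fractions undefined")
    rows = {}
    for cond in CHEM_CONDITIONS:
        cats = classify_edges(series.matrices[cond], threshold)["category"]
        rows[cond] = {
            cat: int((cats == cat).sum()) / n_bic_active for cat in CATEGORIES
        }
    return pd.DataFrame(rows).T[list(CATEGORIES)]


def synchrony_shift_fit(
    reference_scores,
    condition_scores,
) -> dict:
    """OLS line of best fit of condition scores against BIC reference scores.

    Only edges with a finite score in both conditions enter the fit.
    Returns ``{"slope", "intercept", "n"}``; with fewer than 2 common
    edges the fit is missing (NaN slope/intercept).
    """
    x = np.asarray(reference_scores, dtype=float)
    y = np.asarray(condition_scores, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0:
        return {"slope": float("nan"), "intercept": float("nan"), "n": int(x.size)}
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    return {"slope": float(slope), "intercept": float(intercept), "n": int(x.size)}


def synchrony_shift_fits(
    series: TreatmentSeries,
    grouping: str = "within_between",
    reference: str = "BIC",
) -> dict:
    """Shift fits per group for each non-reference condition.

    ``grouping='within_between'`` fits within-section and between-section
    edges separately; ``'per_section'`` fits each cross section's
    within-section edges.  Returns
    ``{condition: {group: {"slope", "intercept", "n"}}}``.
    """
    ref_edges = classify_edges(series.matrices[reference])
    out = {}
    for cond in CHEM_CONDITIONS:
        if cond == reference:
            continue
        cond_edges = classify_edges(series.matrices[cond])
        groups = {}
        if grouping == "within_between":
            masks = {
                "within": ref_edges["within_section"].to_numpy(),
                "between": ~ref_edges["within_section"].to_numpy(),
            }
        elif grouping == "per_section":
            masks = {
                s: (
                    ref_edges["within_section"] & (ref_edges["section_i"] == s)
                ).to_numpy()
                for s in ("bottom", "middle1", "middle2", "top")
            }
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
        for name, m in masks.items():
            groups[name] = synchrony_shift_fit(
                ref_edges.loc[m, "score"], cond_edges.loc[m, "score"]
            )
        out[cond] = groups
    return out


def track_edges(series: TreatmentSeries, threshold: float = HIGH_SYNCHRONY_THRESHOLD) -> pd.DataFrame:
    """Per-edge trajectory across the treatment sequence.

    One row per electrode pair with the score and category under every
    condition plus transition flags: ``became_active`` (inactive at
    baseline, active in a later condition) and ``became_inactive`` (active
    at baseline, inactive later).
    """
    per_cond = {
        cond: classify_edges(series.matrices[cond], threshold)
        for cond in CHEM_CONDITIONS
    }
    base = per_cond["baseline"][["i", "j", "section_i", "section_j", "within_section"]].copy()
    for cond in CHEM_CONDITIONS:
        base[f"score_{cond}"] = per_cond[cond]["score"]
        base[f"category_{cond}"] = per_cond[cond]["category"]
    cats = np.column_stack(
        [per_cond[c]["category"].to_numpy() for c in CHEM_CONDITIONS]
    )
    active = cats != "inactive"
    base["became_active"] = ~active[:, 0] & active[:, 1:].any(axis=1)
    base["became_inactive"] = active[:, 0] & ~active[:, 1:].all(axis=1)
    return base
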