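"""Cross-section aggregation, cell-density normalization and growth/plateau
layer correlations.

Electrode pairs segment the tissue into four 250-um cross sections.
Features are summarized per section (over all 20 electrodes, or over the
active subset), and can be normalized by the cell density of each section:
densities are referenced to the bottom section and inverted, so a section
with a quarter of the bottom's cells gets its activity scaled by 4 — i.e.,
activity per unit cell density.  Layer correlation matrices compare the
per-DIV trajectories of section means within the growth (DIV 14-28) and
plateau (DIV 32-45) phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bursts import FEATURE_COLUMNS
from .geometry import SECTIONS, DeviceLayout

GROWTH_PHASE = (14.0, 28.0)
PLATEAU_PHASE = (32.0, 45.0)


@dataclass(frozen=True)
class DensityProfile:
    """Per-section cell densities derived from a nuclei z-stack.

    ``densities`` are cells/mm^2 per 250-um section (bottom -> top);
    ``constants`` are the normalization constants: density of the bottom
    section divided by the density of each section (bottom = 1), i.e., the
    fold-difference in cell density relative to the bottom.
    """

    densities: tuple
    constants: tuple

    @classmethod
    def from_counts(
        cls,
        slice_edges_um,
        counts,
        field_area_mm2: float = 1.0,
        layout: DeviceLayout | None = None,
    ) -> "DensityProfile":
        """Bin per-z-slice nuclei counts into the electrode cross sections.

        Slices are assigned to the section whose 250-um span contains their
        center; counts above the last section are folded into the top
        section (no extrapolation).
        """
        layout = layout or DeviceLayout()
        edges = np.asarray(slice_edges_um, dtype=float)
        counts = np.asarray(counts, dtype=float)
        if counts.size != edges.size - 1:
            raise ValueError("need one count per slice (len(edges) - 1)")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        span = layout.section_span_um
        centers = (edges[:-1] + edges[1:]) / 2.0
        idx = np.clip((centers // span).astype(int), 0, len(SECTIONS) - 1)
        section_counts = np.bincount(idx, weights=counts, minlength=len(SECTIONS))
        densities = section_counts / field_area_mm2
        constants = density_constants(densities)
        return cls(tuple(densities), tuple(constants))


def density_constants(section_densities) -> np.ndarray:
    """Normalization constants from per-section densities (bottom -> top).

    Each section's density is divided by the bottom density, then inverted,
    giving the fold-difference in cell density: ``c_s = d_bottom / d_s``.
    The bottom constant is 1 by construction.
    """
    d = np.asarray(section_densities, dtype=float)
    if d.shape != (len(SECTIONS),):
        raise ValueError(f"expected {len(SECTIONS)} section densities")
    if np.any(d <= 0):
        raise ValueError("every section needs positive density (fold undefined at 0)")
    return d[0] / d


def aggregate(
    features: pd.DataFrame,
    mode: str = "active_only",
) -> pd.DataFrame:
    """Per-section and full-array feature means from a feature table.

    ``mode='active_only'`` (default) averages over electrodes with
    ``active=True``; ``'zero_filled'`` averages the zero-filled rows over
    all electrodes of the section.  Returns one row per section plus a
    ``"full"`` row, with mean, SEM and electrode counts per feature.
    """
    if mode not in ("active_only", "zero_filled"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    df = features if mode == "zero_filled" else features[features["active"]]
    rows = []
    for section in SECTIONS + ("full",):
        sub = df if section == "full" else df[df["section"] == section]
        pop = features if section == "full" else features[features["section"] == section]
        row = {"section": section, "n_electrodes": len(sub),
               "n_active": int(pop["active"].sum()), "empty": len(sub) == 0}
        for col in FEATURE_COLUMNS:
            if len(sub):
                row[f"{col}_mean"] = float(sub[col].mean())
                row[f"{col}_sem"] = (
                    float(sub[col].std(ddof=1) / np.sqrt(len(sub)))
                    if len(sub) > 1 else 0.0
                )
            else:  # no active electrode in this section
                row[f"{col}_mean"] = 0.0
                row[f"{col}_sem"] = 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("section")


def apply_density_normalization(
    summary: pd.DataFrame,
    constants,
) -> pd.DataFrame:
    """Scale each section's feature means by its density constant.

    Activity in sparse upper sections is inflated by their fold-difference
    in cell density, expressing features per unit cell density.  The
    ``"full"`` row, if present, is left untouched.
    """
    constants = np.asarray(constants, dtype=float)
    if constants.shape != (len(SECTIONS),):
        raise ValueError(f"expected {len(SECTIONS)} constants")
    out = summary.copy()
    cols = [c for c in out.columns if c.endswith(("_mean", "_sem"))]
    for section, c in zip(SECTIONS, constants):
        if section in out.index:
            out.loc[section, cols] = out.loc[section, cols].astype(float) * c
    return out


def phase_correlation(
    summaries: dict,
    feature: str = "firing_rate",
    phases: dict | None = None,
    method: str = "pearson",
) -> dict:
    """Section-by-section correlation of feature trajectories per phase.

    ``summaries`` maps DIV -> aggregated summary (from :func:`aggregate`);
    for each phase window the per-DIV mean-feature vectors of the four
    sections are correlated pairwise (Pearson by default, Spearman
    selectable).  A section whose trajectory is constant within a phase has
    undefined correlations, reported as NaN.  Each phase needs at least 3
    timepoints.

    Returns ``{phase_name: DataFrame (4x4, sections x sections)}``.
    """
    phases = phases or {"growth": GROWTH_PHASE, "plateau": PLATEAU_PHASE}
    col = f"{feature}_mean"
    out = {}
    for name, (lo, hi) in phases.items():
        divs = sorted(d for d in summaries if lo <= d <= hi)
        if len(divs) < 3:
            raise ValueError(
                f"phase {name!r} has {len(divs)} timepoints in [{lo}, {hi}]; need >= 3"
            )
        traj = pd.DataFrame(
            {s: [summaries[d].loc[s, col] for d in divs] for s in SECTIONS},
            index=divs,
        )
        corr = traj.corr(method=method)
        np.fill_diagonal(corr.values, 1.0)
        out[name] = corr
    return out
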