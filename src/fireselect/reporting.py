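"""Summary tables and distribution figures.

Two tabular products mirror the analysis outputs: a sample-accounting table
(per ownership: share of the study area, share of total area burned, and
fire counts by fire type, where a fire counts for every ownership available
to it) and a preference-ranking table (per fire type and ownership: the
fraction f of fires using the class above availability, the overall
permutation P, and the preferred / proportionally used / avoided decision,
ordered by decreasing preference). The figure product is a violin summary
of the Jacobs' index distribution per ownership and fire type.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import FIRE_TYPES, FireTypeLabel
from .geometry import FireFootprint, ProportionTable
from .io_formats import OwnershipLayer, StudyArea, logger
from .proportional_use import OverallTestResult
from .selectivity import SelectivityRecord, SelectivitySummary

__all__ = [
    "SampleAccounting",
    "sample_accounting",
    "ranking_table",
    "render_violin",
]


@dataclass(frozen=True)
class SampleAccounting:
    owner_class: str
    pct_of_study_area: float
    pct_of_total_area_burned: float
    n_forest: int
    n_grass_shrub: int
    n_mixed: int
    n_total: int


def sample_accounting(
    footprints: Sequence[FireFootprint],
    labels: Sequence[FireTypeLabel] | Mapping[str, str],
    proportions: Sequence[ProportionTable],
    ownership: OwnershipLayer,
    study: StudyArea,
) -> list[SampleAccounting]:
    """Per-ownership area shares and fire sample sizes.

    A fire is associated with an ownership if the class occurs anywhere in
    its available area (used, buffer, or both), so each fire contributes a
    count to several classes. Burned area per class is reconstructed as
    ``o_i x used_area`` from the overlay proportions.
    """
    if not isinstance(labels, Mapping):
        labels = {lab.footprint_id: lab.fire_type for lab in labels}
    used_area = {fp.footprint_id: fp.used_polygon.area for fp in footprints}
    class_area = {c: g.area for c, g in ownership.class_geometries().items()}
    study_area = study.boundary.area
    covered = sum(
        g.intersection(study.boundary).area for g in ownership.class_geometries().values()
    )
    gap = study_area - covered
    if gap / study_area > 1e-9:
        class_area["other"] = class_area.get("other", 0.0) + gap

    burned_by: dict[str, float] = {}
    counts: dict[str, dict[str, int]] = {}
    total_burned = 0.0
    for tab in proportions:
        ftype = labels.get(tab.footprint_id)
        a = used_area.get(tab.footprint_id)
        if a is None:
            logger.warning("%s: proportions without a footprint; skipped", tab.footprint_id)
            continue
        total_burned += a
        for owner_class, o, pi in tab.rows:
            burned_by[owner_class] = burned_by.get(owner_class, 0.0) + o * a
            if ftype is not None:
                counts.setdefault(owner_class, {t: 0 for t in FIRE_TYPES})
                counts[owner_class][ftype] += 1

    classes = sorted(set(class_area) | set(burned_by) | set(counts))
    rows = []
    for c in classes:
        by_type = counts.get(c, {t: 0 for t in FIRE_TYPES})
        rows.append(
            SampleAccounting(
                owner_class=c,
                pct_of_study_area=100.0
                * class_area.get(c, 0.0)
                / study_area,
                pct_of_total_area_burned=(
                    100.0 * burned_by.get(c, 0.0) / total_burned if total_burned else 0.0
                ),
                n_forest=by_type["forest"],
                n_grass_shrub=by_type["grass_shrub"],
                n_mixed=by_type["mixed"],
                n_total=sum(by_type.values()),
            )
        )
    return rows


def ranking_table(results: Mapping[str, OverallTestResult]) -> pd.DataFrame:
    """Preference-ranking rows (one per fire type x ownership), ranked."""
    rows = []
    for ftype in sorted(results):
        res = results[ftype]
        tests = {tj.owner_class: tj for tj in res.tests}
        for owner_class in res.ranking:
            tj = tests[owner_class]
            rows.append(
                {
                    "fire_type": ftype,
                    "owner_class": owner_class,
                    "f_statistic": tj.f,
                    "n": tj.n,
                    "p_binomial": tj.p_binomial,
                    "overall_p": res.overall_p,
                    "decision": res.decisions[owner_class],
                }
            )
    return pd.DataFrame(rows)


def render_violin(
    summaries: Sequence[SelectivitySummary],
    records: Sequence[SelectivityRecord],
    out_path: str | Path,
    display_min_n: int = 25,
    jitter_seed: int = 0,
) -> Path | None:
    """Violin figure of Jacobs' index distributions, one panel per fire type.

    Per ownership: a reflected-Gaussian kernel silhouette (Silverman
    bandwidth, support clipped to [-1, 1]), jittered observations, an IQR
    bar, the median dot and the 95% median-CI whisker. Ownerships with
    fewer than ``display_min_n`` observations are omitted. Returns the
    written path, or None for empty input.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = [s for s in summaries if s.n >= display_min_n]
    if not shown:
        logger.warning("render_violin: nothing to draw (all groups below n=%d)", display_min_n)
        return None
    by_type: dict[str, list[SelectivitySummary]] = {}
    for s in shown:
        by_type.setdefault(s.fire_type, []).append(s)
    values: dict[tuple[str, str], list[float]] = {}
    for r in records:
        values.setdefault((r.fire_type, r.owner_class), []).append(r.jacobs)

    rng = np.random.default_rng(jitter_seed)
    fig, axes = plt.subplots(
        1, len(by_type), figsize=(4.0 * len(by_type) + 1.0, 4.5), squeeze=False,
        sharey=True,
    )
    grid = np.linspace(-1.0, 1.0, 256)
    for ax, ftype in zip(axes[0], sorted(by_type)):
        group = sorted(by_type[ftype], key=lambda s: s.owner_class)
        for pos, s in enumerate(group):
            x = np.asarray(values[(ftype, s.owner_class)], dtype=float)
            dens = _reflected_kde(x, grid)
            if dens is not None:
                half = 0.42 * dens / dens.max()
                ax.fill_betweenx(grid, pos - half, pos + half, color="0.8", lw=0)
            jitter = (rng.random(x.size) - 0.5) * 0.5
            ax.plot(pos + jitter, x, ".", color="firebrick", ms=3, alpha=0.6)
            ax.vlines(pos, s.q1, s.q3, color="black", lw=4)
            ax.vlines(pos, s.median_ci_low, s.median_ci_high, color="black", lw=1)
            ax.plot(pos, s.median, "o", color="white", mec="black", zorder=5)
        ax.axhline(0.0, color="0.5", lw=0.5, ls="--")
        ax.set_xticks(range(len(group)))
        ax.set_xticklabels([s.owner_class for s in group], rotation=45, ha="right")
        ax.set_title(f"{ftype} fires")
        ax.set_ylim(-1.1, 1.1)
    axes[0][0].set_ylabel("Jacobs' selectivity index")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def _reflected_kde(x: np.ndarray, grid: np.ndarray) -> np.ndarray | None:
    """Gaussian KDE with Silverman bandwidth, reflected at the ±1 support."""
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        return None  # degenerate spike; points and bars still show it
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    a = min(sd, iqr / 1.349) if iqr > 0 else sd
    bw = 0.9 * a * n ** (-1.0 / 5.0)
    pts = np.concatenate([x, 2.0 - x, -2.0 - x])  # reflect at +1 and -1
    d = np.exp(-0.5 * ((grid[:, None] - pts[None, :]) / bw) ** 2).sum(axis=1)
    d /= n * bw * np.sqrt(2.0 * np.pi)
    return d
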