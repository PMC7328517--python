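"""Cross-assay statistics: marks vs expression, activation-time enrichment.

Links each gene to its nearest classified element (a documented stand-in
for region-to-gene association rules) and reports Pearson correlations
between log-scaled element mark signal and log-scaled expression per
(mark, phase, element class), plus activation-class composition of tagged
gene sets (e.g. bone-specific genes) against the full gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cisre import CisElement
from .core_io import GeneModel
from .eurna import ACTIVATION_CLASSES

LOG_PSEUDOCOUNT = 0.1
ENHANCER_DISTANCE_CAP = 100_000  # bp; nearest-TSS link cap for enhancers


@dataclass(frozen=True)
class CorrelationCell:
    mark: str
    phase: str
    klass: str
    r: float
    n: int
    ci_low: float
    ci_high: float


def pearson_with_ci(x: np.ndarray, y: np.ndarray,
                    alpha: float = 0.05) -> tuple[float, float, float]:
    """Pearson R with a Fisher-z 95% CI."""
    r = float(stats.pearsonr(x, y).statistic)
    n = len(x)
    if n < 4 or abs(r) >= 1.0:
        return r, np.nan, np.nan
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    return r, float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))


def gene_element_signal(elements: list[CisElement],
                        signal_by_element: dict[tuple, dict],
                        klass: str,
                        distance_cap: int | None = None) -> pd.DataFrame:
    """Per-gene signal of its nearest element of one class.

    ``signal_by_element`` maps (chrom, start, end) to a dict of
    (mark, phase) -> signal. When several elements of the class point to
    the same gene, the closest one wins. Enhancer links beyond the
    distance cap are dropped.
    """
    if distance_cap is None and klass != "promoter":
        distance_cap = ENHANCER_DISTANCE_CAP
    best: dict[str, tuple[int, dict]] = {}
    for el in elements:
        if el.klass != klass or el.nearest_gene is None:
            continue
        if distance_cap is not None and el.nearest_distance > distance_cap:
            continue
        sig = signal_by_element.get((el.chrom, el.start, el.end))
        if sig is None:
            continue
        prev = best.get(el.nearest_gene)
        if prev is None or el.nearest_distance < prev[0]:
            best[el.nearest_gene] = (el.nearest_distance, sig)
    rows = []
    for gid, (_, sig) in best.items():
        row = {"gene_id": gid}
        row.update({f"{m}|{p}": v for (m, p), v in sig.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def corr_marks_expression(elements: list[CisElement],
                          signal_by_element: dict[tuple, dict],
                          expression: pd.Series,
                          activation: pd.DataFrame,
                          target_class: str,
                          klasses=("promoter", "active_enhancer"),
                          pseudocount: float = LOG_PSEUDOCOUNT
                          ) -> list[CorrelationCell]:
    """Pearson R between element mark signal and expression of genes in one
    first-activation class, on log2(x + c) scales, per mark x phase x
    element class. Cells with n < 3 usable genes are reported empty
    (NaN R)."""
    if target_class not in ACTIVATION_CLASSES:
        raise ValueError(f"unknown activation class {target_class!r}")
    sel = activation.loc[activation["first_active"] == target_class,
                         "gene_id"]
    expr = expression.reindex(sel).dropna()
    cells: list[CorrelationCell] = []
    for klass in klasses:
        table = gene_element_signal(elements, signal_by_element, klass)
        if table.empty:
            continue
        table = table.set_index("gene_id")
        common = expr.index.intersection(table.index)
        y = np.log2(expr.loc[common].to_numpy(dtype=float) + pseudocount)
        for col in table.columns:
            mark, phase = col.split("|")
            x = np.log2(table.loc[common, col].to_numpy(dtype=float)
                        + pseudocount)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                cells.append(CorrelationCell(mark, phase, klass, np.nan,
                                             int(ok.sum()), np.nan, np.nan))
                continue
            r, lo, hi = pearson_with_ci(x[ok], y[ok])
            cells.append(CorrelationCell(mark, phase, klass, r,
                                         int(ok.sum()), lo, hi))
    return cells


def correlation_frame(cells: list[CorrelationCell]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in cells])


def plot_correlation_grid(cells: list[CorrelationCell], path,
                          title: str = "mark signal vs expression "
                                       "(Pearson R)") -> None:
    """Render the (mark x phase) x element-class R grid as a heat map."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = correlation_frame(cells)
    if frame.empty:
        raise ValueError("no correlation cells to plot")
    frame["row"] = frame["mark"] + " / " + frame["phase"]
    grid = frame.pivot_table(index="row", columns="klass", values="r")
    fig, ax = plt.subplots(
        figsize=(2 + 1.6 * grid.shape[1], 1 + 0.45 * grid.shape[0]))
    im = ax.imshow(grid.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r",
                   aspect="auto")
    ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=30,
                  ha="right")
    ax.set_yticks(range(grid.shape[0]), grid.index)
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            v = grid.to_numpy()[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center",
                        fontsize=8)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8, label="R")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def timepoint_enrichment(activation: pd.DataFrame,
                         genes: list[GeneModel],
                         tag: str,
                         restrict_to: pd.Series | None = None
                         ) -> pd.DataFrame:
    """Activation-class composition of tagged genes vs all genes.

    Per class: fraction of tagged genes first activated there, fraction
    of all genes, their ratio, and a Wilson 95% CI on the tagged
    fraction. Fractions are over each gene universe, so they sum to 1
    and are invariant to duplicating untagged genes. ``restrict_to``
    optionally limits both universes to genes flagged True (e.g.
    mitotic-AE-associated genes from the bookmarking table).
    """
    tagged_ids = {g.gene_id for g in genes if tag in g.tags}
    if not tagged_ids:
        raise ValueError(f"no genes carry tag {tag!r}")
    calls = activation[activation["first_active"] != "excluded"]
    if restrict_to is not None:
        keep = set(restrict_to.index[restrict_to])
        calls = calls[calls["gene_id"].isin(keep)]
    is_tagged = calls["gene_id"].isin(tagged_ids)
    n_tag = int(is_tagged.sum())
    n_all = len(calls)
    rows = []
    for cls in ACTIVATION_CLASSES:
        in_cls = calls["first_active"] == cls
        k_tag = int((in_cls & is_tagged).sum())
        k_all = int(in_cls.sum())
        f_tag = k_tag / n_tag if n_tag else np.nan
        f_all = k_all / n_all if n_all else np.nan
        lo, hi = (proportion_confint(k_tag, n_tag, method="wilson")
                  if n_tag else (np.nan, np.nan))
        rows.append({
            "first_active": cls,
            "frac_tagged": f_tag,
            "frac_all": f_all,
            "ratio": f_tag / f_all if f_all else np.nan,
            "tagged_ci_low": lo,
            "tagged_ci_high": hi,
            "n_tagged": k_tag,
            "n_all": k_all,
        })
    return pd.DataFrame(rows)
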