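"""Cell-level quality control and heavy-chain isotype assignment.

QC retains cells with a low mitochondrial fraction, a total RNA count
inside a fixed window, and zero counts of non-plasma-cell lineage marker
genes (T/NK/myeloid/erythroid/stromal). Isotype assignment combines the
VDJ library (authoritative when a constant-region call exists) with a
GEX fallback based on IGHC transcript counts: the top subclass must hold
a strict majority of summed IGHC counts and strictly exceed a minimum
count, otherwise the cell stays unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clonotyping import C_CALL_TO_SUBCLASS

#: IGHC subclass genes in a fixed canonical order
IGHC_GENES = ("IGHM", "IGHD", "IGHG1", "IGHG2", "IGHG3", "IGHG4",
              "IGHA1", "IGHA2", "IGHE")

#: contaminating-lineage marker genes excluded from the plasma-cell pool
LINEAGE_GENES = ("CD3E", "NKG7", "PRF1", "S100A9", "FCGR3A", "CD14",
                 "COL1A1", "APOE", "CSF3R", "HBB")

SUBCLASS_TO_CLASS = {
    "IgM": "IgM", "IgD": "IgD", "IgE": "IgE",
    "IgG1": "IgG", "IgG2": "IgG", "IgG3": "IgG", "IgG4": "IgG",
    "IgA1": "IgA", "IgA2": "IgA",
}


@dataclass(frozen=True)
class QCThresholds:
    """Cell-retention thresholds.

    mito_max: maximum mitochondrial fraction (exclusive; cells at or above
    are removed). rna_min/rna_max: inclusive bounds on total RNA counts.
    lineage_genes: marker genes that must have zero counts.
    """
    mito_max: float = 0.05
    rna_min: int = 200
    rna_max: int = 4000
    lineage_genes: tuple[str, ...] = LINEAGE_GENES

    def __post_init__(self):
        if self.mito_max <= 0 or self.rna_min <= 0 or self.rna_max <= 0:
            raise ValueError("QC thresholds must be positive")
        if self.rna_min > self.rna_max:
            raise ValueError("rna_min must not exceed rna_max")


@dataclass(frozen=True)
class IsotypeRules:
    """GEX-fallback assignment rules.

    majority_fraction: the top subclass's share of summed IGHC counts must
    STRICTLY exceed this (default 1/2). min_counts: the top subclass count
    must STRICTLY exceed this (default 20).
    """
    majority_fraction: float = 0.5
    min_counts: int = 20


def qc_filter(
    cells: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply cell QC; return retained cells and per-rule removal counts.

    ``cells`` is indexed by barcode with at least ``mito_fraction`` and
    ``total_rna`` columns plus one count column per configured lineage
    gene (absent lineage genes are treated as zero). A removed cell is
    attributed to its FIRST failing rule in the fixed order
    mito -> rna -> lineage, so the counts partition the removed set.
    """
    mito_fail = cells["mito_fraction"] >= thresholds.mito_max
    rna_fail = (cells["total_rna"] < thresholds.rna_min) | (
        cells["total_rna"] > thresholds.rna_max
    )
    present = [g for g in thresholds.lineage_genes if g in cells.columns]
    if present:
        lineage_fail = (cells[present] > 0).any(axis=1)
    else:
        lineage_fail = pd.Series(False, index=cells.index)

    first_fail = np.select(
        [mito_fail, rna_fail & ~mito_fail, lineage_fail & ~mito_fail & ~rna_fail],
        ["mito", "rna", "lineage"],
        default="",
    )
    removed = pd.Series(first_fail, index=cells.index)
    retained = cells[removed == ""]
    counts = {
        "mito": int((removed == "mito").sum()),
        "rna": int((removed == "rna").sum()),
        "lineage": int((removed == "lineage").sum()),
    }
    return retained, counts


def qc_flags(cells: pd.DataFrame,
             thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """Per-cell QC verdict: ``qc_pass`` flag and ``failing_rule`` label."""
    retained, _ = qc_filter(cells, thresholds)
    out = pd.DataFrame(index=cells.index)
    out["qc_pass"] = out.index.isin(retained.index)
    mito_fail = cells["mito_fraction"] >= thresholds.mito_max
    rna_fail = (cells["total_rna"] < thresholds.rna_min) | (
        cells["total_rna"] > thresholds.rna_max
    )
    present = [g for g in thresholds.lineage_genes if g in cells.columns]
    lineage_fail = (cells[present] > 0).any(axis=1) if present else pd.Series(
        False, index=cells.index)
    out["failing_rule"] = np.select(
        [mito_fail, rna_fail, lineage_fail], ["mito", "rna", "lineage"], default=""
    )
    out.loc[out["qc_pass"], "failing_rule"] = ""
    return out


def _gex_call(ighc_counts: np.ndarray, rules: IsotypeRules) -> str | None:
    """GEX-only subclass call from a vector of IGHC counts (IGHC_GENES order).

    Returns the subclass, or None when unassignable (no counts, no strict
    majority, count not above min_counts, or an argmax tie).
    """
    total = ighc_counts.sum()
    if total <= 0:
        return None
    top = ighc_counts.max()
    winners = np.flatnonzero(ighc_counts == top)
    if len(winners) != 1:
        return None  # tie -> unassigned
    if top / total <= rules.majority_fraction:
        return None
    if top <= rules.min_counts:
        return None
    return C_CALL_TO_SUBCLASS[IGHC_GENES[winners[0]]]


def assign_isotype(
    ighc_counts: dict[str, float] | pd.Series,
    c_call: str | None = None,
    rules: IsotypeRules = IsotypeRules(),
) -> tuple[str, str, str]:
    """Assign one cell's isotype; returns (subclass, class, provenance).

    A VDJ constant-region call takes precedence over any GEX evidence;
    otherwise the GEX majority rules apply. Unassignable cells return
    ``("unassigned", "unassigned", "none")``.

    Raises
    ------
    ValueError
        For a constant-region call outside the recognized IGHC names.
    """
    if c_call is not None and isinstance(c_call, str) and c_call != "":
        if c_call not in C_CALL_TO_SUBCLASS:
            raise ValueError(
                f"unknown constant-region call {c_call!r}; accepted: "
                + ", ".join(sorted(C_CALL_TO_SUBCLASS))
            )
        sub = C_CALL_TO_SUBCLASS[c_call]
        return sub, SUBCLASS_TO_CLASS[sub], "VDJ"
    counts = np.array(
        [float(dict(ighc_counts).get(g, 0.0)) for g in IGHC_GENES])
    sub = _gex_call(counts, rules)
    if sub is None:
        return "unassigned", "unassigned", "none"
    return sub, SUBCLASS_TO_CLASS[sub], "GEX"


def assign_isotypes(
    cells: pd.DataFrame,
    vdj: pd.DataFrame | None = None,
    rules: IsotypeRules = IsotypeRules(),
) -> pd.DataFrame:
    """Vectorized isotype assignment for a cell table.

    ``cells`` is indexed by barcode with IGHC gene count columns (missing
    IGHC genes count as zero). ``vdj`` supplies ``cell_id``/``c_call``
    pairs; barcodes absent from it fall back to GEX.

    Returns a DataFrame indexed like ``cells`` with columns
    ``isotype_subclass``, ``isotype_class`` and ``provenance``.
    """
    c_calls: dict[str, str] = {}
    if vdj is not None and len(vdj):
        with_c = vdj[vdj["c_call"].notna() & (vdj["c_call"].astype(str) != "")]
        c_calls = dict(zip(with_c["cell_id"].astype(str), with_c["c_call"]))
        unknown = set(c_calls.values()) - set(C_CALL_TO_SUBCLASS)
        if unknown:
            raise ValueError(
                f"unknown constant-region call(s) {sorted(unknown)}; accepted: "
                + ", ".join(sorted(C_CALL_TO_SUBCLASS))
            )
    mat = np.column_stack([
        cells[g].to_numpy(float) if g in cells.columns else np.zeros(len(cells))
        for g in IGHC_GENES
    ])
    subs, classes, provs = [], [], []
    for bc, row in zip(cells.index.astype(str), mat):
        if bc in c_calls:
            sub = C_CALL_TO_SUBCLASS[c_calls[bc]]
            subs.append(sub)
            classes.append(SUBCLASS_TO_CLASS[sub])
            provs.append("VDJ")
            continue
        sub = _gex_call(row, rules)
        if sub is None:
            subs.append("unassigned")
            classes.append("unassigned")
            provs.append("none")
        else:
            subs.append(sub)
            classes.append(SUBCLASS_TO_CLASS[sub])
            provs.append("GEX")
    return pd.DataFrame(
        {"isotype_subclass": subs, "isotype_class": classes, "provenance": provs},
        index=cells.index,
    )


def benchmark_isotype_inference(
    cells: pd.DataFrame,
    vdj: pd.DataFrame,
    rules: IsotypeRules = IsotypeRules(),
) -> pd.DataFrame:
    """Benchmark the GEX-only inference against VDJ truth.

    For every cell holding a VDJ constant-region call, the GEX rules are
    applied while ignoring the VDJ call; accuracy is the fraction of
    GEX-ASSIGNED cells whose call matches the VDJ subclass, overall and
    per subclass. Cells the GEX rules leave unassigned are tabulated
    separately (``n_gex_unassigned``), not counted as errors.
    Specificity per subclass s = fraction of GEX-assigned cells whose VDJ
    truth is not s that were also not called s.

    Returns one row per subclass plus an ``overall`` row, with columns
    n_vdj, n_gex_assigned, n_gex_unassigned, n_correct, accuracy,
    specificity (accuracy/specificity as percent).

    Raises
    ------
    ValueError
        If no cell carries both a VDJ call and GEX counts.
    """
    with_c = vdj[vdj["c_call"].notna() & (vdj["c_call"].astype(str) != "")]
    truth = {
        str(bc): C_CALL_TO_SUBCLASS[c]
        for bc, c in zip(with_c["cell_id"], with_c["c_call"])
        if c in C_CALL_TO_SUBCLASS
    }
    idx = [bc for bc in cells.index.astype(str) if bc in truth]
    if not idx:
        raise ValueError("no cells with both VDJ isotype and GEX counts")
    sub = cells.loc[idx]
    calls = assign_isotypes(sub, vdj=None, rules=rules)
    df = pd.DataFrame({
        "truth": [truth[bc] for bc in idx],
        "gex": calls["isotype_subclass"].to_numpy(),
    }, index=idx)
    assigned = df[df["gex"] != "unassigned"]

    rows = []
    subclasses = sorted(set(df["truth"]))
    for s in subclasses:
        t = df[df["truth"] == s]
        a = assigned[assigned["truth"] == s]
        n_correct = int((a["gex"] == s).sum())
        neg = assigned[assigned["truth"] != s]
        spec = (100.0 * (neg["gex"] != s).mean()) if len(neg) else np.nan
        rows.append({
            "subclass": s,
            "n_vdj": len(t),
            "n_gex_assigned": len(a),
            "n_gex_unassigned": len(t) - len(a),
            "n_correct": n_correct,
            "accuracy": 100.0 * n_correct / len(a) if len(a) else np.nan,
            "specificity": spec,
        })
    n_correct = int((assigned["gex"] == assigned["truth"]).sum())
    rows.append({
        "subclass": "overall",
        "n_vdj": len(df),
        "n_gex_assigned": len(assigned),
        "n_gex_unassigned": len(df) - len(assigned),
        "n_correct": n_correct,
        "accuracy": 100.0 * n_correct / len(assigned) if len(assigned) else np.nan,
        "specificity": np.nan,
    })
    return pd.DataFrame(rows)
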