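"""Input/output and pipeline orchestration.

Reads the three standard inputs (AIRR Rearrangement TSV, a cell x
feature count table as dense TSV or matrix-market triplet, and per-cell
metadata), runs the stages in order — QC, isotype assignment,
clonotyping, structure classification, binning and statistics — and
writes per-cell / per-clone / per-test TSVs plus a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clonotyping as ct
from . import qc as qcmod
from . import stats as st
from . import structure as struct

logger = logging.getLogger(__name__)

AIRR_REQUIRED_COLUMNS = (
    "cell_id", "v_call", "j_call", "junction_aa", "sequence",
    "germline_alignment",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Declarative configuration of a full analysis run.

    Defaults are the canonical thresholds of the analysis: <5%%
    mitochondrial fraction, 200–4,000 total RNAs, strict->1/2 majority
    and >20-count GEX isotype rules, 0.85 CDR3 similarity cut-off,
    30/40/30 rank bins, >=5-cell clonal families for family-level
    analyses, and 20/100 extreme-family selections.
    """
    # inputs
    vdj_path: str | None = None
    counts_path: str | None = None
    counts_features_path: str | None = None
    counts_barcodes_path: str | None = None
    metadata_path: str | None = None
    outdir: str = "results"
    seed: int = 0
    # QC
    mito_max: float = 0.05
    rna_min: int = 200
    rna_max: int = 4000
    lineage_genes: tuple[str, ...] = qcmod.LINEAGE_GENES
    # isotype rules
    majority_fraction: float = 0.5
    min_counts: int = 20
    # clonotyping
    distance_cutoff: float = 0.85
    distance_semantics: str = "similarity"
    junction_column: str = "junction_aa"
    # binning
    bin_low: float = 0.3
    bin_mid: float = 0.4
    bin_high: float = 0.3
    # family-level analyses
    family_min_size: int = 5
    extreme_family_k: tuple[int, ...] = (20, 100)
    predominance_cut: float = 0.30
    # features
    cd19_feature: str = "CD19_ADT"
    association_gene: str = "JCHAIN"
    allow_missing_features: bool = False

    def __post_init__(self):
        if abs(self.bin_low + self.bin_mid + self.bin_high - 1.0) > 1e-9:
            raise ValueError("binning fractions must sum to 1")
        if not 0.0 <= self.distance_cutoff <= 1.0:
            raise ValueError("distance_cutoff must be in [0, 1]")
        if self.family_min_size < 2:
            raise ValueError("family_min_size must be >= 2")
        if self.distance_semantics not in ("similarity", "distance"):
            raise ValueError("distance_semantics must be similarity|distance")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("lineage_genes", "extreme_family_k"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lineage_genes"] = list(self.lineage_genes)
        d["extreme_family_k"] = list(self.extreme_family_k)
        return d


def read_airr(path: str | Path) -> pd.DataFrame:
    """Read an AIRR Rearrangement TSV.

    Rows missing a junction or V/J call are retained but flagged via a
    boolean ``complete`` column; row order is preserved.

    Raises
    ------
    ValueError
        Naming any required columns that are absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in AIRR_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"AIRR file {path} lacks required column(s): "
                         + ", ".join(missing))
    if "c_call" not in df.columns:
        df["c_call"] = pd.NA
    df["complete"] = (
        df["junction_aa"].notna() & (df["junction_aa"].astype(str) != "")
        & df["v_call"].notna() & df["j_call"].notna()
    )
    return df


def read_count_matrix(
    path: str | Path,
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> pd.DataFrame:
    """Read a cell x feature count table.

    Dense delimited form: a TSV with barcodes in the first column and one
    column per feature. Matrix-market form: pass the ``.mtx`` path plus
    feature and barcode list files (one name per line; cells are rows).

    Raises
    ------
    ValueError
        On duplicated barcodes (the offending barcode is named).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if features_path is None or barcodes_path is None:
            raise ValueError("matrix-market input needs features and barcodes files")
        from scipy import io as spio
        mat = spio.mmread(str(path)).toarray()
        features = pd.read_csv(features_path, sep="\t", header=None)[0].tolist()
        barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].tolist()
        df = pd.DataFrame(mat, index=barcodes, columns=features)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "barcode"
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate barcode in count matrix: {dup!r}")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-cell metadata (TSV, barcode-indexed)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "barcode"
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate barcode in metadata: {dup!r}")
    return df


def get_feature(cells: pd.DataFrame, name: str,
                allow_missing: bool = False) -> pd.Series:
    """Look a feature column up by name.

    An absent feature reads as all-zero only when ``allow_missing`` is
    set; otherwise it is an error.
    """
    if name in cells.columns:
        return cells[name].astype(float)
    if allow_missing:
        logger.warning("feature %r absent; read as zero", name)
        return pd.Series(0.0, index=cells.index, name=name)
    raise ValueError(f"feature {name!r} not present in count matrix")


@dataclass
class PipelineResult:
    """All tables produced by one pipeline run."""
    per_cell: pd.DataFrame
    per_clone: pd.DataFrame
    stats_tables: dict[str, pd.DataFrame]
    test_results: list[st.TestResult]
    qc_removals: dict[str, int]
    benchmark: pd.DataFrame | None
    config: PipelineConfig

    @property
    def tests_table(self) -> pd.DataFrame:
        return pd.DataFrame([t.to_row() for t in self.test_results])


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(
    config: PipelineConfig,
    vdj: pd.DataFrame | None = None,
    cells: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
) -> PipelineResult:
    """Execute QC -> isotype -> clonotyping -> structure -> binning/stats.

    Inputs may be passed as in-memory tables (as the simulator emits
    them) or read from the paths in ``config``. Each stage's output feeds
    the next; a failing stage aborts with its name in the error message.
    """
    # ---- load -----------------------------------------------------------
    @_stage("load")
    def load():
        v, c, m = vdj, cells, meta
        if v is None:
            if not config.vdj_path:
                raise ValueError(
                    "no VDJ input: clonotyping requires vdj_path or an "
                    "in-memory rearrangement table")
            v = read_airr(config.vdj_path)
        if c is None:
            if not config.counts_path:
                raise ValueError("no count-matrix input")
            c = read_count_matrix(config.counts_path,
                                  config.counts_features_path,
                                  config.counts_barcodes_path)
        if m is None:
            if not config.metadata_path:
                raise ValueError("no metadata input")
            m = read_metadata(config.metadata_path)
        return v.copy(), c, m

    vdj_df, cells_df, meta_df = load()

    # ---- qc -------------------------------------------------------------
    @_stage("qc")
    def run_qc():
        merged = meta_df.join(cells_df, how="inner")
        if len(merged) < len(meta_df):
            logger.warning("%d metadata barcodes lack counts",
                           len(meta_df) - len(merged))
        thresholds = qcmod.QCThresholds(
            mito_max=config.mito_max, rna_min=config.rna_min,
            rna_max=config.rna_max, lineage_genes=tuple(config.lineage_genes))
        retained, removals = qcmod.qc_filter(merged, thresholds)
        flags = qcmod.qc_flags(merged, thresholds)
        return merged, retained, removals, flags

    merged, retained, removals, flags = run_qc()

    # ---- isotype --------------------------------------------------------
    @_stage("isotype")
    def run_isotype():
        rules = qcmod.IsotypeRules(config.majority_fraction, config.min_counts)
        calls = qcmod.assign_isotypes(retained, vdj=vdj_df, rules=rules)
        try:
            bench = qcmod.benchmark_isotype_inference(retained, vdj_df, rules)
        except ValueError:
            bench = None
        return calls, bench

    isotype_calls, benchmark = run_isotype()

    # ---- clonotype ------------------------------------------------------
    @_stage("clonotype")
    def run_clonotype():
        sub = vdj_df[vdj_df["cell_id"].astype(str).isin(retained.index)]
        return ct.clonotype_table(
            sub, cutoff=config.distance_cutoff,
            semantics=config.distance_semantics,
            junction_column=config.junction_column)

    clonotypes = run_clonotype()

    # ---- structure ------------------------------------------------------
    @_stage("structure")
    def run_structure():
        fams = struct.build_family_table(clonotypes)
        return fams

    families = run_structure()

    # ---- binning & statistics ------------------------------------------
    @_stage("stats")
    def run_stats():
        per_cell = pd.DataFrame(index=merged.index)
        for col in ("donor", "batch", "allergy_status"):
            if col in merged.columns:
                per_cell[col] = merged[col]
        per_cell = per_cell.join(flags)
        per_cell = per_cell.join(isotype_calls)
        cl = clonotypes.set_index(clonotypes["cell_id"].astype(str))
        per_cell["clone_id"] = cl["clone_id"]
        per_cell["shm_percent"] = cl["shm_percent"]
        structure_map = families.set_index("clone_id")["structure"]
        per_cell["structure"] = per_cell["clone_id"].map(structure_map)

        cd19 = get_feature(retained, config.cd19_feature,
                           config.allow_missing_features)
        per_cell["cd19_z"] = st.normalize_adt(cd19, retained["batch"])
        fractions = (config.bin_low, config.bin_mid, config.bin_high)
        measured = per_cell["cd19_z"].dropna()
        per_cell["cd19_bin"] = st.assign_bins(measured, fractions)
        with_shm = per_cell["shm_percent"].dropna()
        per_cell["shm_bin"] = st.assign_bins(with_shm, fractions)

        tests, tables = _statistics_battery(per_cell, families, retained, config)
        return per_cell, tests, tables

    per_cell, test_results, stats_tables = run_stats()

    per_clone = _decorate_families(families, per_cell, config)
    stats_tables["qc_removals"] = pd.DataFrame(
        [{"rule": k, "removed": v} for k, v in removals.items()])
    if benchmark is not None:
        stats_tables["isotype_benchmark"] = benchmark

    return PipelineResult(
        per_cell=per_cell.rename_axis("barcode"),
        per_clone=per_clone, stats_tables=stats_tables,
        test_results=test_results, qc_removals=removals,
        benchmark=benchmark, config=config)


def _decorate_families(families: pd.DataFrame, per_cell: pd.DataFrame,
                       config: PipelineConfig) -> pd.DataFrame:
    """Attach CD19-bin fractions, predominance and isotype counts per clone."""
    out = families.copy()
    fracs, predominant, iso_counts = [], [], []
    grouped = per_cell[per_cell["clone_id"].notna()].groupby("clone_id")
    by_clone = {cid: grp for cid, grp in grouped}
    for cid in out["clone_id"]:
        grp = by_clone.get(cid)
        bins = list(grp["cd19_bin"].dropna()) if grp is not None else []
        if bins:
            (fl, fm, fh), label = struct.family_cd19_composition(
                bins, config.predominance_cut, config.predominance_cut)
        else:
            (fl, fm, fh), label = (np.nan, np.nan, np.nan), "neither"
        fracs.append((fl, fm, fh))
        predominant.append(label)
        if grp is not None:
            counts = grp["isotype_class"].value_counts().to_dict()
        else:
            counts = {}
        iso_counts.append(json.dumps(counts, sort_keys=True))
    out[["frac_cd19_low", "frac_cd19_mid", "frac_cd19_high"]] = pd.DataFrame(
        fracs, index=out.index)
    out["predominant_cd19"] = predominant
    out["isotype_class_counts"] = iso_counts
    return out


def _statistics_battery(per_cell: pd.DataFrame, families: pd.DataFrame,
                        retained: pd.DataFrame, config: PipelineConfig):
    """Every rank-based association the pipeline reports, one row per test."""
    tests: list[st.TestResult] = []
    tables: dict[str, pd.DataFrame] = {}

    def groups_by(df: pd.DataFrame, value: str, by: str,
                  order=st.BIN_LABELS) -> dict[str, np.ndarray]:
        out = {}
        for label in order:
            vals = df.loc[df[by] == label, value].dropna().to_numpy()
            if len(vals):
                out[label] = vals
        return out

    # SHM across CD19 bins
    g = groups_by(per_cell, "shm_percent", "cd19_bin")
    if len(g) >= 3:
        tests.append(st.rank_test(g, "kruskal_wallis", name="shm_by_cd19_bin"))

    # normalized CD19 across SHM bins
    g = groups_by(per_cell, "cd19_z", "shm_bin")
    if len(g) >= 3:
        tests.append(st.rank_test(g, "kruskal_wallis", name="cd19_by_shm_bin"))

    # SHM-bin composition of each CD19 bin (frequency table)
    both = per_cell.dropna(subset=["cd19_bin", "shm_bin"])
    if len(both):
        tab = pd.crosstab(both["cd19_bin"], both["shm_bin"], normalize="index")
        tables["shm_bin_by_cd19_bin"] = tab.reset_index()

    # SHM across clone structures
    g = {s: per_cell.loc[per_cell["structure"] == s, "shm_percent"]
         .dropna().to_numpy() for s in struct.STRUCTURES}
    g = {k: v for k, v in g.items() if len(v)}
    if len(g) >= 3:
        tests.append(st.rank_test(g, "kruskal_wallis", name="shm_by_structure"))
    elif len(g) == 2:
        tests.append(st.rank_test(g, "mann_whitney", name="shm_by_structure"))

    # heterogenic-clone frequency across CD19 bins (per-donor samples)
    sub = per_cell.dropna(subset=["cd19_bin", "structure"])
    if "donor" in sub.columns and len(sub):
        freq = (sub.assign(het=sub["structure"] == "heterogenic")
                .groupby(["donor", "cd19_bin"], observed=True)["het"].mean()
                .reset_index())
        g = {b: freq.loc[freq["cd19_bin"] == b, "het"].to_numpy()
             for b in st.BIN_LABELS}
        g = {k: v for k, v in g.items() if len(v)}
        if len(g) >= 3 and min(len(v) for v in g.values()) >= 2:
            tests.append(st.rank_test(g, "kruskal_wallis",
                                      name="heterogenic_freq_by_cd19_bin"))
        tables["heterogenic_freq_by_donor_bin"] = freq

    # isotype composition across CD19 bins + per-donor Friedman per subclass
    iso = per_cell.dropna(subset=["cd19_bin"])
    iso = iso[iso["isotype_subclass"] != "unassigned"]
    if len(iso):
        tables["isotype_by_cd19_bin"] = pd.crosstab(
            iso["cd19_bin"], iso["isotype_class"], normalize="index").reset_index()
        if "donor" in iso.columns:
            for subclass in ("IgM", "IgG1", "IgA1"):
                blocks = _donor_bin_frequencies(iso, subclass)
                if blocks is not None:
                    tests.append(st.rank_test(
                        blocks, "friedman",
                        name=f"{subclass}_freq_by_cd19_bin_friedman"))

    # isotype composition within clone structures
    labeled = per_cell.dropna(subset=["structure"])
    labeled = labeled[labeled["isotype_class"] != "unassigned"]
    if len(labeled):
        frac, counts = struct.structure_isotype_frequencies(labeled)
        tables["structure_isotype_fractions"] = frac.reset_index()
        tables["structure_isotype_counts"] = counts.reset_index()

    # CD19 vs SHM correlation
    pair = per_cell.dropna(subset=["cd19_z", "shm_percent"])
    if len(pair) >= 3 and pair["shm_percent"].nunique() > 1:
        rho, p = st.spearman_correlation(pair["cd19_z"], pair["shm_percent"])
        tests.append(st.TestResult(
            name="cd19_shm_spearman", kind="spearman",
            group_labels=["cd19_z", "shm_percent"], group_sizes=[len(pair)] * 2,
            statistic=rho, pvalue=p, method="asymptotic"))

    # association gene across CD19 bins and structures
    gene = config.association_gene
    try:
        expr = np.log1p(get_feature(retained, gene, config.allow_missing_features))
        grouped = per_cell["cd19_bin"]
        res, summary = st.gene_bin_association(
            expr, grouped, name=f"{gene.lower()}_by_cd19_bin")
        tests.append(res)
        tables[f"{gene.lower()}_by_cd19_bin"] = summary
        res, summary = st.gene_bin_association(
            expr, per_cell["structure"], name=f"{gene.lower()}_by_structure")
        tests.append(res)
        tables[f"{gene.lower()}_by_structure"] = summary
    except ValueError as exc:
        logger.warning("association-gene analysis skipped: %s", exc)

    # extreme heterogenic families
    fam = _decorate_families(families, per_cell, config)
    for k in config.extreme_family_k:
        try:
            top, bottom = struct.select_extreme_families(
                fam, k=k, min_size=config.family_min_size)
        except ValueError as exc:
            logger.warning("extreme-family selection (k=%d) skipped: %s", k, exc)
            continue
        top = top.assign(extreme="most_mutated")
        bottom = bottom.assign(extreme="least_mutated")
        tables[f"extreme_families_k{k}"] = pd.concat([top, bottom],
                                                     ignore_index=True)
        a = top["frac_cd19_high"].dropna().to_numpy()
        b = bottom["frac_cd19_high"].dropna().to_numpy()
        if len(a) >= 2 and len(b) >= 2:
            tests.append(st.rank_test(
                {"most_mutated": a, "least_mutated": b}, "mann_whitney",
                name=f"cd19_high_frac_extreme_families_k{k}"))

    return tests, tables


def _donor_bin_frequencies(iso: pd.DataFrame, subclass: str):
    """Per-donor frequency of one subclass in each CD19 bin, Friedman-ready.

    Returns {bin: vector over donors} with complete blocks only, or None
    when fewer than 2 donors have cells in every bin or the subclass is
    absent.
    """
    if (iso["isotype_subclass"] == subclass).sum() == 0:
        return None
    freq = (iso.assign(hit=iso["isotype_subclass"] == subclass)
            .groupby(["donor", "cd19_bin"], observed=True)["hit"].mean()
            .unstack("cd19_bin"))
    freq = freq.dropna()
    if len(freq) < 2 or freq.shape[1] < 3:
        return None
    return {b: freq[b].to_numpy() for b in st.BIN_LABELS if b in freq.columns}


def write_results(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write all result tables as TSV plus a JSON run manifest."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise PipelineError(f"cannot create output directory {outdir}: {exc}")
    paths: dict[str, Path] = {}
    paths["per_cell"] = outdir / "per_cell.tsv"
    result.per_cell.to_csv(paths["per_cell"], sep="\t")
    paths["per_clone"] = outdir / "per_clone.tsv"
    result.per_clone.to_csv(paths["per_clone"], sep="\t", index=False)
    paths["tests"] = outdir / "tests.tsv"
    result.tests_table.to_csv(paths["tests"], sep="\t", index=False)
    stats_dir = outdir / "stats"
    stats_dir.mkdir(exist_ok=True)
    for name, table in result.stats_tables.items():
        p = stats_dir / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths[f"stats/{name}"] = p
    for t in result.test_results:
        if t.posthoc is not None:
            p = stats_dir / f"{t.name}_posthoc.tsv"
            t.posthoc.to_csv(p, sep="\t", index=False)
            paths[f"stats/{t.name}_posthoc"] = p
    cfg = result.config.to_dict()
    manifest = {
        "seed": result.config.seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "qc_removals": result.qc_removals,
        "n_cells": int(len(result.per_cell)),
        "n_clones": int(len(result.per_clone)),
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
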