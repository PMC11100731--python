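"""Synthetic paired VDJ + GEX + CITE-seq repertoire generator.

Emulates a CD138-sorted bone-marrow plasma-cell dataset in which every
cell descends from one of two planted ancestries:

* **MBC recall** — memory-B-cell progeny: lower somatic hypermutation,
  clone members copy one heavy-chain sequence identically (isogenic
  clones or singlets), lower surface CD19, higher JCHAIN.
* **GC export** — direct germinal-center emigrants: higher SHM, clone
  members differ by private mutations (heterogenic clones), higher
  surface CD19.

The generator emits the three tables the analysis pipeline ingests — an
AIRR-dialect rearrangement table, a cell x feature count table (IGHC
subclass genes, lineage markers, a CD19 antibody-capture feature and an
association gene), and per-cell metadata — plus a ground-truth record of
origins, clone ids and isotypes so every downstream stage is verifiable.

Clone CDR3s are rejection-sampled to keep any two clones' junctions at
hamming distance >= 3 (junction lengths 10–18 aa keep 3 mismatches above
the default 0.15 normalized-distance threshold), so clone recovery is
well-posed by construction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .qc import IGHC_GENES, LINEAGE_GENES

SUBCLASSES = ("IgM", "IgD", "IgG1", "IgG2", "IgG3", "IgG4", "IgA1", "IgA2", "IgE")
SUBCLASS_TO_C_CALL = {
    "IgM": "IGHM", "IgD": "IGHD", "IgG1": "IGHG1", "IgG2": "IGHG2",
    "IgG3": "IGHG3", "IgG4": "IGHG4", "IgA1": "IGHA1", "IgA2": "IGHA2",
    "IgE": "IGHE",
}

CD19_FEATURE = "CD19_ADT"
ASSOCIATION_GENE = "JCHAIN"

_NT = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# Per-origin heavy-chain class/subclass priors. MBC progeny lean IgM/IgG
# (long-lived peripheral IgM and IgG memory); GC exports lean IgA
# (mucosal germinal centers feed plasma-cell output directly).
DEFAULT_ISOTYPE_PROBS: dict[str, dict[str, float]] = {
    "MBC": {"IgM": 0.25, "IgD": 0.02, "IgG1": 0.30, "IgG2": 0.12, "IgG3": 0.05,
            "IgG4": 0.03, "IgA1": 0.15, "IgA2": 0.07, "IgE": 0.01},
    "GC": {"IgM": 0.08, "IgD": 0.01, "IgG1": 0.22, "IgG2": 0.10, "IgG3": 0.04,
           "IgG4": 0.03, "IgA1": 0.35, "IgA2": 0.15, "IgE": 0.02},
}

DEFAULT_QC_FAIL_RATES: dict[str, float] = {
    "mito": 0.02, "rna_low": 0.01, "rna_high": 0.01, "lineage": 0.02,
}


def _panel(rng: np.random.Generator, n: int, length: int, prefix: str) -> dict[str, str]:
    return {
        f"{prefix}{i + 1}-1*01": "".join(rng.choice(_NT, length))
        for i in range(n)
    }


# Fixed synthetic germline panel: 12 V and 6 J templates with distinct
# names, generated once from a hard-coded seed so they behave as bundled
# constants. Allele suffixes (*01) exercise allele stripping downstream.
_panel_rng = np.random.default_rng(20_240_817)
GERMLINE_V: dict[str, str] = _panel(_panel_rng, 12, 288, "SIMHV")
GERMLINE_J: dict[str, str] = {
    f"SIMHJ{i + 1}*01": "".join(_panel_rng.choice(_NT, 48)) for i in range(6)
}
del _panel_rng


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the synthetic repertoire.

    SHM means/sds are in percent mutated nucleotides; ``cd19_effect`` is
    the between-origin difference of normalized (log, per-batch Z-scored)
    surface CD19 in Z units; ``jchain_effect`` is the shift in mean
    log1p JCHAIN counts of MBC-origin over GC-origin cells;
    ``intraclonal_mut_rate_gc`` is the Poisson mean of private (per-cell)
    mutations inside GC-origin clones, while MBC-origin clone members
    copy one sequence identically.
    """
    n_cells: int = 2000
    n_donors: int = 9
    frac_allergic_donors: float = 6 / 9
    origin_mix: float = 0.5          # probability a clone is GC-export
    clone_size_zeta: float = 2.5     # P(size=s) ~ s^-zeta, s = 1..max
    clone_size_max: int = 50
    shm_mbc_mean: float = 4.0
    shm_mbc_sd: float = 1.5
    shm_gc_mean: float = 8.0
    shm_gc_sd: float = 2.0
    intraclonal_mut_rate_gc: float = 2.0
    cd19_effect: float = 1.5
    isotype_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {o: dict(p) for o, p in DEFAULT_ISOTYPE_PROBS.items()})
    isotype_dispersion: float = 0.0  # >0: per-donor Dirichlet jitter of the priors
    ighc_count_mean: float = 100.0
    ambient_rate: float = 0.5
    vdj_dropout: float = 0.1
    qc_fail_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_QC_FAIL_RATES))
    jchain_effect: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_allergic_donors", "origin_mix", "vdj_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_cells < 1 or self.n_donors < 1:
            raise ValueError("n_cells and n_donors must be positive")
        if self.clone_size_max < 1 or self.clone_size_zeta <= 1:
            raise ValueError("invalid clone size distribution")
        for origin, probs in self.isotype_probs.items():
            if set(probs) != set(SUBCLASSES):
                raise ValueError(f"isotype_probs[{origin!r}] must cover all subclasses")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"isotype_probs[{origin!r}] sums to {total}, expected 1")
        for rule, rate in self.qc_fail_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"qc_fail_rates[{rule!r}] must be in [0, 1]")
        p = self.origin_mix
        if p * (1 - p) * self.cd19_effect ** 2 >= 1.0:
            raise ValueError("cd19_effect too large for this origin mix")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ClonePlan:
    """Blueprint for one clonal family before sequences are realized."""
    clone_id: str
    size: int
    origin: str              # "MBC" | "GC"
    donor: int
    isotype: str
    shm_target: float        # percent
    extra_muts: list[int]    # per-member private mutation counts (0s for MBC)


@dataclass
class SimResult:
    """Tables emitted by :func:`simulate_repertoire` plus ground truth."""
    cells: pd.DataFrame        # barcode x feature counts
    meta: pd.DataFrame         # barcode-indexed donor/batch/allergy/QC inputs
    vdj: pd.DataFrame          # AIRR-dialect rearrangements
    truth_cells: pd.DataFrame  # barcode, origin, clone id, isotype, planted QC
    truth_clones: pd.DataFrame
    config: SimConfig


def mutate_sequence(germline: str, n_mut: int, rng: np.random.Generator) -> str:
    """Introduce exactly ``n_mut`` point substitutions at distinct positions.

    Every chosen position receives a base different from the germline
    base, so the hamming distance to ``germline`` is exactly ``n_mut``.

    Raises
    ------
    ValueError
        If ``n_mut`` exceeds the sequence length or the sequence contains
        characters outside A/C/G/T.
    """
    if n_mut > len(germline):
        raise ValueError(
            f"n_mut={n_mut} exceeds sequence length {len(germline)}")
    if set(germline) - set("ACGT"):
        raise ValueError("germline must be over the alphabet {A,C,G,T}")
    positions = rng.choice(len(germline), size=n_mut, replace=False)
    return _mutate_at(germline, positions, rng)


def _mutate_at(seq: str, positions, rng: np.random.Generator) -> str:
    chars = list(seq)
    for pos in positions:
        current = chars[pos]
        alternatives = [b for b in "ACGT" if b != current]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


def _sample_clone_size(rng: np.random.Generator, zeta: float, max_size: int) -> int:
    sizes = np.arange(1, max_size + 1)
    probs = sizes ** (-zeta)
    probs /= probs.sum()
    return int(rng.choice(sizes, p=probs))


def sample_family_plan(config: SimConfig, rng: np.random.Generator) -> list[ClonePlan]:
    """Draw clone blueprints until exactly ``n_cells`` cells are planned.

    Each clone draws an origin (GC with probability ``origin_mix``), a
    size from the truncated power law, a donor, an isotype from the
    per-origin prior, and a target SHM level. GC-origin clones of size
    >= 2 are guaranteed at least two distinct per-member private mutation
    loads, so their realized sequences cannot all coincide; MBC-origin
    clones plan zero private mutations (one shared sequence).
    """
    donor_probs = _donor_isotype_tables(config, rng)
    plans: list[ClonePlan] = []
    total = 0
    idx = 0
    while total < config.n_cells:
        origin = "GC" if rng.random() < config.origin_mix else "MBC"
        size = _sample_clone_size(rng, config.clone_size_zeta, config.clone_size_max)
        size = min(size, config.n_cells - total)
        donor = int(rng.integers(config.n_donors))
        probs = donor_probs[(donor, origin)]
        isotype = str(rng.choice(SUBCLASSES, p=probs))
        if origin == "GC":
            mean, sd = config.shm_gc_mean, config.shm_gc_sd
            extras = list(rng.poisson(config.intraclonal_mut_rate_gc, size).astype(int))
            if size >= 2 and len(set(extras)) < 2:
                extras[-1] += 1
        else:
            mean, sd = config.shm_mbc_mean, config.shm_mbc_sd
            extras = [0] * size
        shm_target = float(max(0.0, rng.normal(mean, sd)))
        plans.append(ClonePlan(
            clone_id=f"tclone_{idx:05d}", size=size, origin=origin, donor=donor,
            isotype=isotype, shm_target=shm_target, extra_muts=extras))
        total += size
        idx += 1
    return plans


def _donor_isotype_tables(config: SimConfig, rng: np.random.Generator):
    """Per-(donor, origin) subclass probability vectors.

    With ``isotype_dispersion == 0`` every donor shares the configured
    prior; otherwise donor tables are Dirichlet draws around it.
    """
    tables = {}
    for donor in range(config.n_donors):
        for origin in ("MBC", "GC"):
            base = np.array([config.isotype_probs[origin][s] for s in SUBCLASSES])
            if config.isotype_dispersion > 0:
                alpha = np.maximum(base, 1e-6) / config.isotype_dispersion
                tables[(donor, origin)] = rng.dirichlet(alpha)
            else:
                tables[(donor, origin)] = base
    return tables


def _sample_cdr3(rng: np.random.Generator,
                 accepted: dict[int, list[str]]) -> str:
    """A junction at hamming distance >= 3 from all accepted same-length ones."""
    for _ in range(10_000):
        length = int(rng.integers(10, 19))
        cand = "".join(rng.choice(_AA, length))
        ok = all(
            sum(a != b for a, b in zip(cand, prev)) >= 3
            for prev in accepted.get(length, ())
        )
        if ok:
            accepted.setdefault(length, []).append(cand)
            return cand
    raise RuntimeError("could not place a well-separated CDR3; "
                       "too many clones for the junction space")


def simulate_repertoire(config: SimConfig) -> SimResult:
    """Generate one synthetic repertoire with full ground truth.

    Deterministic: an identical config (including seed) yields identical
    tables. See the module docstring for the generative model.
    """
    rng = np.random.default_rng(config.seed)
    plans = sample_family_plan(config, rng)
    n = config.n_cells

    v_names = list(GERMLINE_V)
    j_names = list(GERMLINE_J)
    accepted_cdr3: dict[int, list[str]] = {}

    # realize per-clone germlines and member sequences, in plan order
    cell_rows = []   # per-cell dicts, later shuffled by barcode assignment
    clone_rows = []
    for plan in plans:
        v_call = v_names[rng.integers(len(v_names))]
        j_call = j_names[rng.integers(len(j_names))]
        cdr3 = _sample_cdr3(rng, accepted_cdr3)
        junction_nt = "".join(rng.choice(_NT, 3 * len(cdr3)))
        germline = GERMLINE_V[v_call] + junction_nt + GERMLINE_J[j_call]
        seq_len = len(germline)
        trunk_n = min(int(round(plan.shm_target / 100.0 * seq_len)), seq_len)
        trunk_positions = rng.choice(seq_len, size=trunk_n, replace=False)
        trunk_seq = _mutate_at(germline, trunk_positions, rng)
        free = np.setdiff1d(np.arange(seq_len), trunk_positions)
        structure = ("singlet" if plan.size == 1
                     else "isogenic" if plan.origin == "MBC" else "heterogenic")
        clone_rows.append({
            "clone_id": plan.clone_id, "origin": plan.origin, "size": plan.size,
            "donor": f"donor{plan.donor + 1:02d}", "isotype": plan.isotype,
            "structure_planned": structure, "shm_target": plan.shm_target,
        })
        for member, extra in enumerate(plan.extra_muts):
            extra = min(extra, len(free))
            if extra:
                pos = rng.choice(free, size=extra, replace=False)
                seq = _mutate_at(trunk_seq, pos, rng)
            else:
                seq = trunk_seq
            cell_rows.append({
                "clone_id": plan.clone_id, "origin": plan.origin,
                "donor": plan.donor, "isotype": plan.isotype,
                "v_call": v_call, "j_call": j_call, "junction_aa": cdr3,
                "sequence": seq, "germline": germline,
                "n_mut": trunk_n + extra, "seq_len": seq_len,
            })

    assert len(cell_rows) == n
    # decorrelate barcode order from clone order
    perm = rng.permutation(n)
    barcodes = np.array([f"cell_{perm[i]:06d}" for i in range(n)])
    order = np.argsort(barcodes)

    # per-cell planted QC failures: disjoint sets, chosen at random
    planted_fail = np.array([""] * n, dtype=object)
    fail_order = rng.permutation(n)
    cursor = 0
    for rule in ("mito", "rna_low", "rna_high", "lineage"):
        count = int(round(config.qc_fail_rates.get(rule, 0.0) * n))
        planted_fail[fail_order[cursor:cursor + count]] = rule
        cursor += count

    mito = rng.uniform(0.005, 0.045, n)
    mito[planted_fail == "mito"] = rng.uniform(
        0.055, 0.20, int((planted_fail == "mito").sum()))
    total_rna = rng.integers(400, 3801, n)
    total_rna[planted_fail == "rna_low"] = rng.integers(
        20, 200, int((planted_fail == "rna_low").sum()))
    total_rna[planted_fail == "rna_high"] = rng.integers(
        4100, 8001, int((planted_fail == "rna_high").sum()))

    donors = np.array([r["donor"] for r in cell_rows])
    donor_names = np.array([f"donor{d + 1:02d}" for d in donors])
    batch_names = np.array([f"run{d // 3 + 1}" for d in donors])
    n_allergic = int(round(config.frac_allergic_donors * config.n_donors))
    allergic = donors < n_allergic
    origins = np.array([r["origin"] for r in cell_rows])
    isotypes = np.array([r["isotype"] for r in cell_rows])

    # IGHC counts: Poisson(mean) for the true isotype, Poisson(ambient) others
    counts = {g: rng.poisson(config.ambient_rate, n).astype(float)
              for g in IGHC_GENES}
    for g in IGHC_GENES:
        own = isotypes == {v: k for k, v in SUBCLASS_TO_C_CALL.items()}[g]
        counts[g][own] = rng.poisson(config.ighc_count_mean, int(own.sum()))
    for g in LINEAGE_GENES:
        counts[g] = np.zeros(n)
    lineage_idx = np.flatnonzero(planted_fail == "lineage")
    for i in lineage_idx:
        gene = LINEAGE_GENES[rng.integers(len(LINEAGE_GENES))]
        counts[gene][i] = rng.integers(1, 6)

    # surface CD19 ADT: batch offset + origin shift + unit lognormal noise.
    # The latent shift is pre-compensated for the origin-mixture variance so
    # the post-normalization Z difference matches cd19_effect.
    p = config.origin_mix
    denom = 1.0 - p * (1 - p) * config.cd19_effect ** 2
    d_adj = config.cd19_effect / np.sqrt(denom)
    batch_ids = sorted(set(batch_names))
    batch_offset = {b: 4.5 + rng.normal(0.0, 0.3) for b in batch_ids}
    latent = (np.array([batch_offset[b] for b in batch_names])
              + d_adj * ((origins == "GC").astype(float) - 0.5)
              + rng.normal(0.0, 1.0, n))
    counts[CD19_FEATURE] = rng.poisson(np.exp(latent)).astype(float)

    # association gene: MBC-origin cells shifted up by jchain_effect (log units)
    jc_latent = (np.log(20.0) + config.jchain_effect * (origins == "MBC")
                 + rng.normal(0.0, 0.4, n))
    counts[ASSOCIATION_GENE] = rng.poisson(np.exp(jc_latent)).astype(float)

    has_vdj = np.ones(n, dtype=bool)
    n_drop = int(round(config.vdj_dropout * n))
    if n_drop:
        has_vdj[rng.permutation(n)[:n_drop]] = False

    cells = pd.DataFrame(counts, index=barcodes).iloc[order]
    cells.index.name = "barcode"
    meta = pd.DataFrame({
        "donor": donor_names, "batch": batch_names,
        "allergy_status": allergic, "mito_fraction": mito,
        "total_rna": total_rna,
    }, index=barcodes).iloc[order]
    meta.index.name = "barcode"

    vdj = pd.DataFrame({
        "cell_id": barcodes,
        "v_call": [r["v_call"] for r in cell_rows],
        "j_call": [r["j_call"] for r in cell_rows],
        "junction_aa": [r["junction_aa"] for r in cell_rows],
        "sequence": [r["sequence"] for r in cell_rows],
        "germline_alignment": [r["germline"] for r in cell_rows],
        "c_call": [SUBCLASS_TO_C_CALL[i] for i in isotypes],
    })[has_vdj].iloc[np.argsort(barcodes[has_vdj])].reset_index(drop=True)

    truth_cells = pd.DataFrame({
        "barcode": barcodes,
        "origin": origins,
        "clone_id": [r["clone_id"] for r in cell_rows],
        "isotype": isotypes,
        "n_mut": [r["n_mut"] for r in cell_rows],
        "seq_len": [r["seq_len"] for r in cell_rows],
        "planted_qc_fail": planted_fail,
        "has_vdj": has_vdj,
    }).iloc[order].reset_index(drop=True)
    truth_clones = pd.DataFrame(clone_rows)

    return SimResult(cells=cells, meta=meta, vdj=vdj,
                     truth_cells=truth_cells, truth_clones=truth_clones,
                     config=config)


def write_simulation(sim: SimResult, outdir: str | Path,
                     counts_format: str = "tsv") -> dict[str, Path]:
    """Write all simulator tables plus a JSON run manifest.

    ``counts_format``: ``"tsv"`` for a dense cells x features table or
    ``"mtx"`` for matrix-market triplet + feature/barcode lists.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["vdj"] = outdir / "vdj.tsv"
    sim.vdj.to_csv(paths["vdj"], sep="\t", index=False)
    paths["metadata"] = outdir / "metadata.tsv"
    sim.meta.to_csv(paths["metadata"], sep="\t")
    paths["truth_cells"] = outdir / "truth_cells.tsv"
    sim.truth_cells.to_csv(paths["truth_cells"], sep="\t", index=False)
    paths["truth_clones"] = outdir / "truth_clones.tsv"
    sim.truth_clones.to_csv(paths["truth_clones"], sep="\t", index=False)

    if counts_format == "tsv":
        paths["counts"] = outdir / "counts.tsv"
        sim.cells.to_csv(paths["counts"], sep="\t")
    elif counts_format == "mtx":
        from scipy import io as spio
        from scipy.sparse import csr_matrix
        paths["counts"] = outdir / "counts.mtx"
        spio.mmwrite(str(paths["counts"]), csr_matrix(sim.cells.to_numpy()))
        paths["features"] = outdir / "features.tsv"
        pd.Series(sim.cells.columns).to_csv(paths["features"], sep="\t",
                                            index=False, header=False)
        paths["barcodes"] = outdir / "barcodes.tsv"
        pd.Series(sim.cells.index).to_csv(paths["barcodes"], sep="\t",
                                          index=False, header=False)
    else:
        raise ValueError(f"unknown counts format {counts_format!r}")

    cfg = sim.config.to_dict()
    manifest = {
        "seed": sim.config.seed,
        "n_cells": sim.config.n_cells,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
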