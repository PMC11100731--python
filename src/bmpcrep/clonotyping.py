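"""Somatic-hypermutation quantification and clonal-family assignment.

Heavy-chain rearrangements are grouped into clones the way standard
repertoire tools do it: cells sharing the same IGHV gene, IGHJ gene and
CDR3 (junction) amino-acid length are candidates, and within such a
partition single-linkage clustering joins any two cells whose junctions
are sufficiently similar under normalized hamming distance. SHM is the
percent of mismatched nucleotides between the observed heavy-chain
sequence and its inferred germline over all comparable aligned positions.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: nucleotides that count as comparable in the SHM denominator
_VALID_NT = frozenset("ACGT")

#: isotype subclasses recognized for constant-region calls
C_CALL_TO_SUBCLASS = {
    "IGHM": "IgM",
    "IGHD": "IgD",
    "IGHG1": "IgG1",
    "IGHG2": "IgG2",
    "IGHG3": "IgG3",
    "IGHG4": "IgG4",
    "IGHA1": "IgA1",
    "IGHA2": "IgA2",
    "IGHE": "IgE",
}


def compute_shm(sequence: str, germline: str) -> float:
    """Percent mutation of ``sequence`` relative to ``germline``.

    Both strings must be the same (aligned) length. Positions where either
    string carries an ambiguous base or gap character (anything outside
    A/C/G/T, e.g. ``N``, ``-`` or ``.``) are excluded from numerator and
    denominator.

    Returns ``100 * mismatches / comparable_positions``.

    Raises
    ------
    ValueError
        If the lengths differ or no comparable positions remain.
    """
    if len(sequence) != len(germline):
        raise ValueError(
            f"sequence length {len(sequence)} != germline length {len(germline)}"
        )
    comparable = 0
    mismatches = 0
    for s, g in zip(sequence.upper(), germline.upper()):
        if s in _VALID_NT and g in _VALID_NT:
            comparable += 1
            if s != g:
                mismatches += 1
    if comparable == 0:
        raise ValueError("no comparable (unambiguous, ungapped) positions")
    return 100.0 * mismatches / comparable


def cdr3_distance(a: str, b: str) -> float | None:
    """Normalized hamming distance between two CDR3 amino-acid strings.

    Returns a float in [0, 1], or ``None`` ("incomparable") when the
    strings differ in length or either is empty — length-mismatched
    junctions are never clonally related under the hamming model.
    """
    if not a or not b or len(a) != len(b):
        return None
    mismatches = sum(x != y for x, y in zip(a, b))
    return mismatches / len(a)


def strip_allele(call: str) -> str:
    """Reduce a V/J call to its gene name.

    Drops the allele suffix (``IGHV3-23*01`` -> ``IGHV3-23``) and, when a
    caller reports multiple comma-separated candidates, keeps the first.
    """
    if not isinstance(call, str):
        return ""
    return call.split(",")[0].split("*")[0].strip()


def dedupe_heavy_chains(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one heavy chain per barcode.

    When a barcode carries multiple heavy-chain rows the row with the most
    isotype evidence is kept: rows with a constant-region call win over
    rows without, then longer sequences, then first occurrence. Dropped
    rows are logged.
    """
    if records["cell_id"].is_unique:
        return records
    has_c = records["c_call"].notna() & (records["c_call"].astype(str) != "")
    seq_len = records["sequence"].fillna("").str.len()
    order = pd.DataFrame(
        {"has_c": has_c.astype(int), "seq_len": seq_len}, index=records.index
    )
    ranked = records.assign(_has_c=order["has_c"], _len=order["seq_len"])
    ranked = ranked.sort_values(
        ["cell_id", "_has_c", "_len"], ascending=[True, False, False], kind="stable"
    )
    kept = ranked.drop_duplicates("cell_id", keep="first")
    n_dropped = len(records) - len(kept)
    logger.warning("dropped %d extra heavy-chain rows for multi-chain barcodes", n_dropped)
    kept = kept.drop(columns=["_has_c", "_len"])
    return kept.loc[records.index.intersection(kept.index)]


def annotate_shm(records: pd.DataFrame) -> pd.DataFrame:
    """Add a ``shm_percent`` column from sequence/germline_alignment pairs.

    Rows lacking either string get NaN.
    """
    shm = np.full(len(records), np.nan)
    seqs = records["sequence"].to_numpy()
    germs = records["germline_alignment"].to_numpy()
    for i, (s, g) in enumerate(zip(seqs, germs)):
        if isinstance(s, str) and isinstance(g, str) and s and g:
            shm[i] = compute_shm(s, g)
    out = records.copy()
    out["shm_percent"] = shm
    return out


def cluster_clones(
    records: pd.DataFrame,
    cutoff: float = 0.85,
    semantics: str = "similarity",
    junction_column: str = "junction_aa",
) -> pd.Series:
    """Assign clone ids by V/J-restricted single-linkage CDR3 clustering.

    Records are partitioned by (V gene, J gene, junction length) — allele
    suffixes stripped — and within each partition the single-linkage
    components of the graph with an edge wherever the normalized hamming
    distance between junctions is at most the distance threshold form the
    clones. With the default similarity semantics, ``cutoff=0.85`` means
    two junctions join when they are at least 85% identical (distance
    <= 0.15).

    Parameters
    ----------
    records
        One row per cell with columns ``cell_id``, ``v_call``, ``j_call``
        and the junction column. Rows with a missing junction or V/J call
        are skipped (no clone id).
    cutoff
        Threshold value; its meaning depends on ``semantics``.
    semantics
        ``"similarity"`` (join when 1 - distance >= cutoff) or
        ``"distance"`` (join when distance <= cutoff).

    Returns
    -------
    pandas.Series
        clone id per barcode, indexed by ``cell_id``. Ids are
        ``clone_000001`` … ordered by each clone's smallest member
        barcode, so they are stable under input-order permutations.
    """
    if semantics == "similarity":
        max_dist = 1.0 - cutoff
    elif semantics == "distance":
        max_dist = cutoff
    else:
        raise ValueError(f"unknown distance semantics: {semantics!r}")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")

    usable = records[
        records[junction_column].notna()
        & (records[junction_column].astype(str).str.len() > 0)
        & records["v_call"].notna()
        & records["j_call"].notna()
    ]

    partitions: dict[tuple[str, str, int], list[tuple[str, str]]] = {}
    for cell_id, v, j, junc in zip(
        usable["cell_id"], usable["v_call"], usable["j_call"], usable[junction_column]
    ):
        key = (strip_allele(v), strip_allele(j), len(junc))
        partitions.setdefault(key, []).append((str(cell_id), str(junc)))

    components: list[list[str]] = []
    # epsilon guards float round-off on normalized distances like 1/6
    eps = 1e-12
    for members in partitions.values():
        g = nx.Graph()
        g.add_nodes_from(bc for bc, _ in members)
        n = len(members)
        for i in range(n):
            bi, ji = members[i]
            for k in range(i + 1, n):
                bk, jk = members[k]
                d = cdr3_distance(ji, jk)
                if d is not None and d <= max_dist + eps:
                    g.add_edge(bi, bk)
        components.extend(sorted(comp) for comp in nx.connected_components(g))

    components.sort(key=lambda comp: comp[0])
    assignment: dict[str, str] = {}
    for idx, comp in enumerate(components, start=1):
        cid = f"clone_{idx:06d}"
        for bc in comp:
            assignment[bc] = cid
    out = pd.Series(assignment, name="clone_id")
    out.index.name = "cell_id"
    return out


def clonotype_table(
    records: pd.DataFrame,
    cutoff: float = 0.85,
    semantics: str = "similarity",
    junction_column: str = "junction_aa",
) -> pd.DataFrame:
    """Per-cell clonotype table: barcode, clone id, V/J, CDR3 and SHM.

    Convenience wrapper: dedupes multi-chain barcodes, computes SHM and
    clusters clones in one pass.
    """
    recs = dedupe_heavy_chains(records)
    recs = annotate_shm(recs)
    clones = cluster_clones(recs, cutoff=cutoff, semantics=semantics,
                            junction_column=junction_column)
    out = recs[["cell_id", "v_call", "j_call", junction_column,
                "sequence", "c_call", "shm_percent"]].copy()
    out["clone_id"] = out["cell_id"].map(clones)
    return out.reset_index(drop=True)
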