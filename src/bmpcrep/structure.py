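"""Clonal-family structure classification and family-level composition.

Expanded clones whose members carry non-identical heavy-chain nucleotide
sequences ("heterogenic") are read as direct germinal-center exports;
expanded clones whose members are sequence-identical ("isogenic") as
recall-expanded memory-B-cell progeny; unexpanded cells are singlets.
Family-level composition (CD19-bin fractions, isotype mix, SHM summary)
drives the origin inference downstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRUCTURES = ("singlet", "isogenic", "heterogenic")


def classify_clone_structure(sequences: list[str | None]) -> str:
    """Label one clone from its members' full heavy-chain nucleotide sequences.

    singlet: one cell; isogenic: >= 2 cells, all sequences identical;
    heterogenic: >= 2 cells with >= 2 unique sequences. Identity is exact
    string equality on the full sequence (CDR3-only equality would
    misclassify trunk-mutation variants). Members lacking a sequence are
    excluded with a warning; a clone with no sequenced member is an error.
    """
    usable = [s for s in sequences if isinstance(s, str) and s]
    n_missing = len(sequences) - len(usable)
    if n_missing:
        logger.warning("excluded %d clone member(s) lacking a sequence", n_missing)
    if not usable:
        raise ValueError("clone has no member with a sequence")
    if len(usable) == 1:
        return "singlet"
    return "isogenic" if len(set(usable)) == 1 else "heterogenic"


def build_family_table(clonotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-clone summary from a per-cell clonotype table.

    ``clonotypes`` needs columns cell_id, clone_id, sequence, shm_percent
    (and optionally isotype_class, cd19_bin added by the caller).

    Returns one row per clone: clone_id, size, unique_sequences,
    structure, mean_shm, median_shm.
    """
    df = clonotypes[clonotypes["clone_id"].notna()]
    rows = []
    for cid, grp in df.groupby("clone_id", sort=True):
        seqs = [s for s in grp["sequence"] if isinstance(s, str) and s]
        structure = classify_clone_structure(list(grp["sequence"]))
        shm = grp["shm_percent"].dropna()
        rows.append({
            "clone_id": cid,
            "size": len(grp),
            "unique_sequences": len(set(seqs)),
            "structure": structure,
            "mean_shm": float(shm.mean()) if len(shm) else np.nan,
            "median_shm": float(shm.median()) if len(shm) else np.nan,
        })
    return pd.DataFrame(
        rows, columns=["clone_id", "size", "unique_sequences", "structure",
                       "mean_shm", "median_shm"])


def family_cd19_composition(
    member_bins: list[str],
    low_cut: float = 0.30,
    high_cut: float = 0.30,
) -> tuple[tuple[float, float, float], str]:
    """CD19-bin fractions of one family and its predominance call.

    A family is predominantly CD19-low when strictly more than ``low_cut``
    of its binned members are low AND strictly less than ``high_cut`` are
    high; predominantly high under the symmetric condition; otherwise
    neither. Members without a bin are ignored; a family with no binned
    member is an error.
    """
    binned = [b for b in member_bins if b in ("low", "mid", "high")]
    if not binned:
        raise ValueError("family has no members with a CD19 bin")
    n = len(binned)
    frac_low = binned.count("low") / n
    frac_mid = binned.count("mid") / n
    frac_high = binned.count("high") / n
    if frac_low > low_cut and frac_high < high_cut:
        label = "low"
    elif frac_high > high_cut and frac_low < low_cut:
        label = "high"
    else:
        label = "neither"
    return (frac_low, frac_mid, frac_high), label


def select_extreme_families(
    families: pd.DataFrame,
    k: int,
    min_size: int = 5,
    by: str = "median_shm",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The k most- and k least-mutated heterogenic families.

    Families are filtered to heterogenic structure and ``size >=
    min_size``, ranked by the SHM summary column (default the median of
    member SHM; ties broken by clone_id), and both extremes returned.
    With fewer than 2k eligible families the two lists overlap (warning);
    with fewer than k, each list is all eligible families.

    Raises
    ------
    ValueError
        If no eligible family remains.
    """
    eligible = families[
        (families["structure"] == "heterogenic") & (families["size"] >= min_size)
    ]
    if eligible.empty:
        raise ValueError("no heterogenic families of the required size")
    ranked = eligible.sort_values([by, "clone_id"], ascending=[True, True],
                                  kind="stable")
    if len(ranked) < 2 * k:
        logger.warning(
            "only %d eligible families for k=%d; extreme lists overlap",
            len(ranked), k)
    bottom = ranked.head(min(k, len(ranked)))
    top = ranked.tail(min(k, len(ranked))).iloc[::-1]
    return top.reset_index(drop=True), bottom.reset_index(drop=True)


def structure_isotype_frequencies(
    cells: pd.DataFrame,
    structure_col: str = "structure",
    isotype_col: str = "isotype_class",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Isotype-class composition within each clone-structure category.

    Returns (fractions, counts): contingency tables structure x isotype
    class; each fractions row sums to 1.

    Raises
    ------
    ValueError
        On empty input or missing labels.
    """
    df = cells[[structure_col, isotype_col]].dropna()
    if df.empty:
        raise ValueError("no cells with both structure and isotype labels")
    counts = pd.crosstab(df[structure_col], df[isotype_col])
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return fractions, counts
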