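"""Interpretation of communication patterns: enrichment, networks, abundance.

Pathway enrichment asks whether the ligand-receptor pairs of a pattern
over-represent a pathway relative to all tested pairs, via a one-sided
(upper-tail) Fisher's exact test on the 2x2 membership table. Network
extraction chains pattern pairs to downstream transcription factors and
target genes through receptor-TF and TF-TG edge tables. Cell-type utilities
score spatial co-localization with the bivariate global Moran statistic and
summarize per-pattern cell abundance under the pattern's mean surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ccc import SpatialWeights, global_moran_r

logger = logging.getLogger(__name__)


def fisher_upper_tail_p(overlap: int, universe: int, pathway: int, query: int):
    """One-sided (upper-tail) Fisher's exact p for a 2x2 membership table.

    ``P[X >= overlap]`` with X hypergeometric over ``universe`` items of
    which ``pathway`` are in the pathway and ``query`` are drawn.
    Vectorizes over array arguments.
    """
    return stats.hypergeom.sf(np.asarray(overlap) - 1, universe, pathway, query)


def pathway_enrichment(
    query_pairs: list[str],
    universe_pairs: list[str],
    pair_pathways: dict[str, str],
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Upper-tail Fisher's exact enrichment of pathways in a pair query.

    ``pair_pathways`` maps pair name to pathway. The universe is the set of
    all tested pairs (conditioning on the panel); per pathway the 2x2 table
    is (query & pathway, query \\ pathway, pathway \\ query, neither) and
    ``p = P[overlap >= observed]`` hypergeometric. Rows sorted by p.
    """
    query = list(dict.fromkeys(query_pairs))
    universe = list(dict.fromkeys(universe_pairs))
    if not query:
        raise ValueError("empty query")
    missing = set(query) - set(universe)
    if missing:
        raise ValueError(f"query pairs not in universe: {sorted(missing)[:5]}")
    uni = set(universe)
    qset = set(query)
    rows = []
    pathways = sorted({pair_pathways[p] for p in universe if p in pair_pathways})
    for pw in pathways:
        members = {p for p in universe if pair_pathways.get(p) == pw}
        a = len(qset & members)
        p_val = float(fisher_upper_tail_p(a, len(uni), len(members), len(qset)))
        rows.append(
            dict(
                pathway=pw,
                pairs_in_query=a,
                pairs_in_pathway=len(members),
                query_size=len(qset),
                universe_size=len(uni),
                fraction=a / len(members) if members else np.nan,
                p=p_val,
            )
        )
    out = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    if bh_correct and len(out):
        from statsmodels.stats.multitest import multipletests

        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass
class NetworkModule:
    """Typed edges of an L-R-TF-TG chain for one pattern."""

    lr_edges: pd.DataFrame  # ligand, receptor
    rtf_edges: pd.DataFrame  # receptor, tf [, score]
    tftg_edges: pd.DataFrame  # tf, target

    def to_sif(self, path: str) -> None:
        with open(path, "w") as fh:
            for r in self.lr_edges.itertuples():
                fh.write(f"{r.ligand}\tLR\t{r.receptor}\n")
            for r in self.rtf_edges.itertuples():
                fh.write(f"{r.receptor}\tRTF\t{r.tf}\n")
            for r in self.tftg_edges.itertuples():
                fh.write(f"{r.tf}\tTFTG\t{r.target}\n")


def extract_lr_tf_tg(
    pattern_pairs: list[tuple[str, str]],
    rtf_table: pd.DataFrame,
    tftg_table: pd.DataFrame,
    min_rtf_score: float | None = None,
) -> NetworkModule:
    """Chain pattern LR pairs to downstream TFs and target genes.

    Steps, in order: dedupe ligands/receptors of the pattern pairs; trace
    TFs of those receptors through receptor-TF edges (optionally score-
    thresholded); then collect TF-TG edges of the unique TFs. Modules with
    no matching receptor-TF edge still return their L-R layer.
    """
    if not {"receptor", "tf"} <= set(rtf_table.columns):
        missing = {"receptor", "tf"} - set(rtf_table.columns)
        raise ValueError(f"R-TF table missing column(s): {sorted(missing)}")
    if not {"tf", "target"} <= set(tftg_table.columns):
        missing = {"tf", "target"} - set(tftg_table.columns)
        raise ValueError(f"TF-TG table missing column(s): {sorted(missing)}")
    lr = pd.DataFrame(
        sorted(set(pattern_pairs)), columns=["ligand", "receptor"]
    )
    receptors = sorted(set(lr["receptor"]))
    rtf = rtf_table[rtf_table["receptor"].isin(receptors)]
    if min_rtf_score is not None and "score" in rtf.columns:
        rtf = rtf[rtf["score"] >= min_rtf_score]
    rtf = rtf.drop_duplicates(["receptor", "tf"]).sort_values(
        ["receptor", "tf"], kind="stable"
    ).reset_index(drop=True)
    tfs = sorted(set(rtf["tf"]))
    tftg = (
        tftg_table[tftg_table["tf"].isin(tfs)]
        .drop_duplicates(["tf", "target"])
        .sort_values(["tf", "target"], kind="stable")
        .reset_index(drop=True)
    )
    return NetworkModule(lr_edges=lr, rtf_edges=rtf, tftg_edges=tftg)


def colocalization(
    abundance: np.ndarray,
    type_names: list[str],
    weights: SpatialWeights,
) -> pd.DataFrame:
    """Pairwise cell-type co-localization via global bivariate Moran R.

    Returns one row per unordered type pair (self-pairs included, flagged);
    zero-variance types are excluded with a log entry.
    """
    A = np.asarray(abundance, dtype=float)
    if A.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    usable = [i for i in range(A.shape[1]) if np.ptp(A[:, i]) > 0]
    for i in range(A.shape[1]):
        if i not in usable:
            logger.info("cell type %s excluded: zero variance", type_names[i])
    rows = []
    for ii, i in enumerate(usable):
        for j in usable[ii:]:
            r, z, p = global_moran_r(A[:, i], A[:, j], weights)
            rows.append(
                dict(
                    type_a=type_names[i], type_b=type_names[j],
                    R_global=r, z=z, p=p, self_pair=i == j,
                )
            )
    return pd.DataFrame(rows)


def cell_abundance_per_pattern(
    pattern_means: np.ndarray,
    celltype_by_location: np.ndarray,
    type_names: list[str] | None = None,
) -> pd.DataFrame:
    """Cell-type proportions under each pattern's mean surface.

    Location weights are the pattern's mean surface clipped at zero and
    normalized; abundance is the weighted per-type total, normalized to sum
    1 within each pattern.
    """
    mu = np.asarray(pattern_means, dtype=float)
    types = np.asarray(celltype_by_location, dtype=float)
    if types.min() < 0:
        raise ValueError("negative cell-type abundances")
    if mu.shape[0] != types.shape[0]:
        raise ValueError("locations mismatch between surfaces and abundances")
    out = np.zeros((types.shape[1], mu.shape[1]))
    for c in range(mu.shape[1]):
        w = np.clip(mu[:, c], 0, None)
        tot = w.sum()
        w = w / tot if tot > 0 else np.full_like(w, 1.0 / len(w))
        mass = types.T @ w
        out[:, c] = mass / mass.sum() if mass.sum() > 0 else 0.0
    names = type_names or [f"type{i}" for i in range(types.shape[1])]
    return pd.DataFrame(
        out, index=names, columns=[f"pattern{c}" for c in range(mu.shape[1])]
    )
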