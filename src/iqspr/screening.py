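"""Rank a candidate library against the inversion solution and fuse with
docking-derived ranks.

The first screen is purely descriptor-based: every admissible library ligand
(leverage within the warning limit h*) is ranked by the Euclidean distance of
its raw-unit selected descriptors to the inversion solution x*. A second,
structure-based screen can supply a composite induced-fit docking score
(IFDScore = 1.0·GlideScore + 0.05·Prime Energy) whose rank is averaged with
the descriptor rank (round half up) into a final rank.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data_model import DescriptorTable, ValidationError
from .diagnostics import leverage
from .preprocess import Autoscaler


def euclidean_distances(x_star: np.ndarray, library: DescriptorTable,
                        scaled: bool = False,
                        train_values: np.ndarray | None = None) -> pd.Series:
    """Per-ligand Euclidean distance to x*.

    Distances are computed in raw descriptor units by default (matching the
    published tabulation convention); set ``scaled=True`` with the training
    matrix to compute them on autoscaled descriptors instead.
    """
    x_star = np.asarray(x_star, dtype=float)
    if x_star.shape != (library.n_descriptors,):
        raise ValidationError(
            f"x_star has {x_star.shape} entries, library has "
            f"{library.n_descriptors} descriptors")
    V = library.values
    if scaled:
        if train_values is None:
            raise ValidationError("scaled distances need the training matrix")
        scaler = Autoscaler().fit(train_values)
        V = scaler.transform(V)
        x_star = scaler.transform(x_star[None, :])[0]
    d = np.sqrt(((V - x_star) ** 2).sum(axis=1))
    return pd.Series(d, index=pd.Index(library.compound_ids, name="ligand_id"),
                     name="dist_x")


def admissibility_filter(library: DescriptorTable, train_desc: DescriptorTable,
                         h_star: float) -> pd.Series:
    """Boolean per ligand: leverage within the warning limit h*.

    Leverage is computed on autoscaled selected descriptors, scaling fit on
    the training table.
    """
    if library.descriptor_names != train_desc.descriptor_names:
        raise ValidationError("library/training descriptor sets differ")
    scaler = Autoscaler().fit(train_desc.values)
    h = leverage(scaler.transform(train_desc.values),
                 scaler.transform(library.values))
    return pd.Series(h <= h_star,
                     index=pd.Index(library.compound_ids, name="ligand_id"),
                     name="leverage_ok")


def ifd_score(glide_score, prime_energy):
    """Composite induced-fit docking score, kcal/mol (lower is better)."""
    return np.asarray(glide_score, dtype=float) + 0.05 * np.asarray(
        prime_energy, dtype=float)


def rank_by_distance(dist: pd.Series, admissible: pd.Series | None = None) -> pd.Series:
    """Dense competition-free 1..m rank over admissible ligands, ascending
    distance; ties break lexicographically on ligand id. Inadmissible ligands
    get no rank (NA)."""
    if admissible is None:
        admissible = pd.Series(True, index=dist.index)
    sub = dist[admissible.reindex(dist.index, fill_value=False)]
    ids = np.asarray([str(i) for i in sub.index])
    order = np.lexsort((ids, sub.to_numpy()))
    rank_values = np.empty(len(sub), dtype=int)
    rank_values[order] = np.arange(1, len(sub) + 1)
    ranks = pd.Series(pd.NA, index=dist.index, dtype="Int64", name="iqspr_rank")
    ranks[sub.index] = rank_values
    return ranks


def final_ranking(iqspr_ranks: pd.Series, docking_ranks: pd.Series) -> pd.Series:
    """Fuse the two screens: round-half-up mean of the two ranks per ligand.

    Ligands missing either rank are excluded with a warning. Equal fused
    values intentionally share the same final rank.
    """
    common = iqspr_ranks.dropna().index.intersection(docking_ranks.dropna().index)
    dropped = iqspr_ranks.index.union(docking_ranks.index).difference(common)
    if len(dropped):
        warnings.warn(f"final_ranking: excluded ligands without both ranks: "
                      f"{sorted(map(str, dropped))}", RuntimeWarning, stacklevel=2)
    mean = (iqspr_ranks[common].astype(float) + docking_ranks[common].astype(float)) / 2.0
    fused = np.floor(mean + 0.5).astype(int)  # round half up
    return pd.Series(fused, index=common, name="final_rank")


def screen(x_star: np.ndarray, library: DescriptorTable,
           train_desc: DescriptorTable, h_star: float,
           docking: pd.DataFrame | None = None) -> pd.DataFrame:
    """Full screening table: distance, admissibility, ranks, optional fusion.

    ``docking`` may carry an ``ifd_score`` column or ``glide_score`` /
    ``prime_energy`` component columns (combined internally). Docking ranks
    ascend with the score (more negative = better = rank 1).
    """
    dist = euclidean_distances(x_star, library)
    ok = admissibility_filter(library, train_desc, h_star)
    iqspr_rank = rank_by_distance(dist, ok)
    out = pd.DataFrame({"dist_x": dist, "leverage_ok": ok,
                        "iqspr_rank": iqspr_rank})
    if docking is not None:
        if "ifd_score" in docking.columns:
            score = docking["ifd_score"].astype(float)
        elif {"glide_score", "prime_energy"} <= set(docking.columns):
            score = pd.Series(ifd_score(docking["glide_score"],
                                        docking["prime_energy"]),
                              index=docking.index)
        else:
            raise ValidationError(
                "docking table needs an ifd_score column or glide_score + "
                "prime_energy columns")
        score = score.reindex(out.index)
        docking_rank = rank_by_distance(score.dropna())
        out["docking_score"] = score
        out["docking_rank"] = docking_rank.reindex(out.index)
        fused = final_ranking(out["iqspr_rank"], out["docking_rank"])
        out["final_rank"] = fused.reindex(out.index)
    return out
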