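"""Mapping mutation annotations onto structure and clustering statistics.

A mutation's structural location is the geometric center of the residue it
affects; its radial coordinate relative to a pore point p is
l_mut = ‖p − center‖.  Clustering of mutations relative to the pore-domain
interface is summarized by the per-pore-point mean/median/mode of
{l_mut − l_i} and by the normal fit of the distribution collapsed over all
pore points.  The flipping-coin midpoint l* is the radius at which a
mutation is equally likely to fall inside or outside the ball (the
maximum of the binary entropy −P ln P − (1−P) ln(1−P) at P = 1/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .packing_model import PackingFit, model_n
from .pore_geometry import RadialProfile, ScaleGrid, cumulative_count
from .structure_io import MolecularStructure

__all__ = ["MutationRecord", "ClusteringSummary", "load_mutations",
           "clustering_stats", "entropy_midpoint", "LABEL_VOCAB"]

LABEL_VOCAB = {
    "gof": "GoF", "lof": "LoF", "neutral": "neutral", "benign": "benign",
    "pathogenic": "pathogenic_other", "pathogenic_other": "pathogenic_other",
    "vus": "VUS",
}


@dataclass
class MutationRecord:
    """One annotated mutation resolved against the structure."""
    chain: str
    residue_seq: int
    residue_name: str
    label: str
    center: np.ndarray


def load_mutations(table, structure: MolecularStructure) -> list:
    """Resolve a mutation CSV (chain, residue_seq, residue_name, label).

    Rows whose residue is absent from the structure are skipped with a
    warning; labels outside the vocabulary raise.  Residue centers are
    geometric means over all residue atoms (backbone and hydrogens
    included).
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table)
    required = {"chain", "residue_seq", "residue_name", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"mutation table must have columns {sorted(required)}")

    labels = []
    for raw in df["label"]:
        key = str(raw).strip().lower()
        if key not in LABEL_VOCAB:
            raise ValueError(f"unknown mutation label {raw!r}; expected one "
                             f"of {sorted(set(LABEL_VOCAB.values()))}")
        labels.append(LABEL_VOCAB[key])
    df["label"] = labels

    atom_df = pd.DataFrame({
        "chain": structure.chain, "residue_seq": structure.res_seq,
        "x": structure.coords[:, 0], "y": structure.coords[:, 1],
        "z": structure.coords[:, 2]})
    centers = atom_df.groupby(["chain", "residue_seq"])[["x", "y", "z"]] \
        .mean()

    records, skipped = [], 0
    for row in df.itertuples(index=False):
        key = (str(row.chain), int(row.residue_seq))
        if key not in centers.index:
            skipped += 1
            continue
        records.append(MutationRecord(
            chain=key[0], residue_seq=key[1],
            residue_name=str(row.residue_name), label=row.label,
            center=centers.loc[key].to_numpy()))
    if skipped:
        warnings.warn(f"{skipped} mutation rows referenced residues absent "
                      "from the structure and were skipped")
    return records


def _kde_mode(values: np.ndarray) -> float:
    """Mode via Gaussian KDE (Silverman bandwidth), argmax on a 0.1 Å grid."""
    if np.ptp(values) < 1e-9:
        return float(values[0])
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.arange(values.min(), values.max() + 0.1, 0.1)
    return float(grid[np.argmax(kde(grid))])


@dataclass
class ClusteringSummary:
    """Per-pore-point and collapsed statistics of {l_mut − l_i}."""
    per_pore: pd.DataFrame          # pore_index, mean, median, mode
    collapsed_mean: float
    collapsed_sd: float
    labels_used: tuple


def clustering_stats(mutations, pore_fits, path_points,
                     label_filter=None) -> ClusteringSummary:
    """Mean/median/mode of {l_mut − l_i} per pore point, plus the collapsed
    normal fit (moment estimators) over all pore points and mutations.

    ``pore_fits`` is a sequence of :class:`PackingFit` aligned with
    ``path_points``; non-converged fits are excluded.  ``label_filter``
    restricts to a subset of labels.
    """
    if label_filter is not None:
        subset = [m for m in mutations if m.label in set(label_filter)]
        if not subset:
            raise ValueError(f"no mutations left after filtering on "
                             f"{sorted(set(label_filter))}")
    else:
        subset = list(mutations)
        if not subset:
            raise ValueError("empty mutation list")
    centers = np.array([m.center for m in subset])

    rows, pooled = [], []
    for idx, (p, fit) in enumerate(zip(np.asarray(path_points), pore_fits)):
        if fit is None or not fit.converged:
            continue
        d = np.linalg.norm(centers - p, axis=1) - fit.l_i
        rows.append({"pore_index": idx, "mean": float(np.mean(d)),
                     "median": float(np.median(d)), "mode": _kde_mode(d)})
        pooled.append(d)
    if not rows:
        raise ValueError("no converged pore-point fits")
    pooled = np.concatenate(pooled)
    labels = tuple(sorted({m.label for m in subset}))
    return ClusteringSummary(per_pore=pd.DataFrame(rows),
                             collapsed_mean=float(np.mean(pooled)),
                             collapsed_sd=float(np.std(pooled, ddof=1)),
                             labels_used=labels)


def entropy_midpoint(profile: RadialProfile, fit: PackingFit,
                     grid: ScaleGrid):
    """Flipping-coin midpoint l*: returns ``(l_star_emp, l_star_theo)``.

    Empirical: the smallest grid l with N/n_total ≥ 0.5.  Theoretical: the
    root of n(l)/n(L) = 0.5 on the fitted model.  When n(L) ≈ K the
    theoretical midpoint approaches the characteristic bound l_i,b.
    """
    counts = cumulative_count(profile, grid.l_values)
    frac = counts / profile.n_at_outer
    k = int(np.argmax(frac >= 0.5))
    if frac[k] < 0.5:
        raise ValueError("empirical occupancy never reaches 0.5 on the grid")
    l_emp = float(grid.l_values[k])

    L = profile.outer_radius
    n_L = float(model_n(fit.params, L, fit.l_i))

    def g(l):
        return float(model_n(fit.params, l, fit.l_i)) - 0.5 * n_L

    l_theo = float(optimize.brentq(g, profile.r_bar, L))
    return l_emp, l_theo
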