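"""Synthetic pore-forming atom clouds and mutation datasets with known truth.

The generator draws atom radii about a generating pore point by inverse-CDF
sampling of the closed-form packing law n(l), so every fitted parameter has
a ground truth to recover.  Hydropathy labels follow a radius-dependent
logistic probability of being hydrophilic, emulating the hydrophobic-core
phenomenology of real channels (hydrophobicity buried near the pore point,
hydrophilicity enriched toward the surface).  Atoms are emitted as
single-atom pseudo-residues (PHO/PHI) resolvable by the shipped hydropathy
table, and the cloud is mirror-symmetrized in-plane so the pore axis of the
synthetic channel is exactly the z axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .packing_model import PackingParameters, PackingFit, inflection_point, \
    model_n
from .structure_io import MolecularStructure

__all__ = ["GeneratorConfig", "default_parameters", "sample_structure",
           "sample_mutation_dataset", "philic_probability"]

_CHAINS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_MAX_RES = 9999  # PDB residue-number field width


def default_parameters() -> PackingParameters:
    """Reference truth parameters: ζ=5 Å, ξ=10 Å, K=30000, n0=10, l0=1 Å."""
    return PackingParameters(zeta=5.0, xi=10.0, capacity=30000.0,
                             n0=10.0, l0=1.0)


@dataclass
class GeneratorConfig:
    """Ground-truth configuration of a synthetic atom cloud.

    ``philic_profile`` is (midpoint Å, steepness Å⁻¹) of the logistic
    radius → P(hydrophilic) map; ``l_max`` is the outer sampling radius
    (defaults to the radius where n reaches 99% of K).
    """
    params: PackingParameters = field(default_factory=default_parameters)
    n_total: int = 30000
    # logistic midpoint ≈ 0.8·l_i of the default law: the hydrophobic core
    # spans the pore domain, hydrophilicity is enriched toward the surface,
    # and the overall phobic/philic balance is close to 1:1
    philic_profile: tuple = (40.0, 0.25)
    axis_length: float = 40.0
    seed: int = 0
    l_max: float | None = None
    symmetrize: bool = True

    def __post_init__(self):
        if self.n_total < 1:
            raise ValueError("n_total must be positive")


def philic_probability(r, midpoint: float, steepness: float):
    """Logistic probability that an atom at radius r is hydrophilic."""
    return 1.0 / (1.0 + np.exp(-steepness * (np.asarray(r, float)
                                             - midpoint)))


def _solve_l_max(params: PackingParameters, frac: float = 0.99) -> float:
    l_i = inflection_point(params)
    nu = max(params.nu, 1e-8)
    u = (frac ** (-nu) - 1.0) / nu  # n(l)/K = frac
    return float(l_i - params.xi * np.log(u))


def sample_structure(config: GeneratorConfig):
    """Draw a synthetic structure; returns ``(structure, truth_dict)``.

    Radii are inverse-CDF draws of n(l)/n(l_max) about the origin (the
    generating pore point); directions are uniform on the sphere, emitted in
    mirror pairs (x, y, z)/(−x, −y, z) sharing a radius so in-plane slab
    centers vanish identically.  Weights are set to ±0.5 directly and are
    reproducible through the shipped table (PHO/C → −0.5, PHI/O → +0.5).
    """
    rng = np.random.default_rng(config.seed)
    params = config.params
    l_max = config.l_max if config.l_max is not None else \
        _solve_l_max(params)
    l_i = float(inflection_point(params))

    l_grid = np.linspace(0.0, l_max, 4096)
    n_grid = model_n(params, l_grid, l_i)
    cdf = n_grid / n_grid[-1]

    n = config.n_total
    if config.symmetrize:
        n_pairs, n_rest = divmod(n, 2)
        r_half = np.interp(rng.uniform(cdf[0], 1.0, n_pairs), cdf, l_grid)
        radii = np.concatenate([r_half, r_half])
        d = rng.normal(size=(n_pairs, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        mirror = d * np.array([-1.0, -1.0, 1.0])
        dirs = np.concatenate([d, mirror])
        if n_rest:  # odd atom placed on the axis itself
            radii = np.append(radii,
                              np.interp(rng.uniform(cdf[0], 1.0),
                                        cdf, l_grid))
            dirs = np.vstack([dirs, [0.0, 0.0, 1.0]])
    else:
        radii = np.interp(rng.uniform(cdf[0], 1.0, n), cdf, l_grid)
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    coords = radii[:, None] * dirs

    mid, steep = config.philic_profile
    philic = rng.random(n) < philic_probability(radii, mid, steep)
    weights = np.where(philic, 0.5, -0.5)

    idx = np.arange(n)
    structure = MolecularStructure(
        serial=idx + 1,
        name=np.where(philic, "O", "C").astype("U6"),
        res_name=np.where(philic, "PHI", "PHO").astype("U5"),
        chain=np.array([_CHAINS[i // _MAX_RES] for i in idx], dtype="U4"),
        res_seq=idx % _MAX_RES + 1,
        coords=coords,
        weight=weights.astype(float),
    )
    truth = {
        "zeta": params.zeta, "xi": params.xi, "capacity": params.capacity,
        # the cloud realizes n_total atoms of the mass n(l_max); its own
        # carrying capacity is rescaled accordingly
        "capacity_effective": float(params.capacity * n / n_grid[-1]),
        "n0": params.n0, "l0": params.l0, "nu": params.nu, "l_i": l_i,
        "l_max": float(l_max), "n_total": n, "seed": config.seed,
        "philic_profile": list(config.philic_profile),
    }
    return structure, truth


def sample_mutation_dataset(structure: MolecularStructure, pore_point,
                            fit: PackingFit, n_per_class: int = 150,
                            class_offsets=(-6.0, 1.0), sigma: float = 13.0,
                            labels=("GoF", "neutral"), seed: int = 0):
    """Draw two mutation classes with class-specific radial offsets.

    Each class places ``n_per_class`` pseudo-residue mutations at radii
    l_i + Normal(μ_class, σ) from the pore point, snapped to the
    nearest-radius existing residue; draws outside [R̄, L] are resampled
    (counted).  Returns ``(DataFrame, truth_dict)`` in the mutation CSV
    schema (chain, residue_seq, residue_name, label).
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(pore_point, dtype=float)
    radii = np.linalg.norm(structure.coords - p, axis=1)
    order = np.argsort(radii)
    r_sorted = radii[order]
    r_lo, r_hi = r_sorted[0], r_sorted[-1]

    rows = []
    n_resampled = 0
    for mu, label in zip(class_offsets, labels):
        targets = np.empty(n_per_class)
        for k in range(n_per_class):
            while True:
                t = fit.l_i + rng.normal(mu, sigma)
                if r_lo <= t <= r_hi:
                    targets[k] = t
                    break
                n_resampled += 1
        pos = np.clip(np.searchsorted(r_sorted, targets), 0,
                      len(r_sorted) - 1)
        # snap to whichever neighbor radius is closer
        left = np.clip(pos - 1, 0, len(r_sorted) - 1)
        pick = np.where(np.abs(r_sorted[pos] - targets)
                        <= np.abs(r_sorted[left] - targets), pos, left)
        for i in order[pick]:
            rows.append({"chain": structure.chain[i],
                         "residue_seq": int(structure.res_seq[i]),
                         "residue_name": structure.res_name[i],
                         "label": label})
    df = pd.DataFrame(rows)
    truth = {"class_offsets": list(class_offsets), "sigma": sigma,
             "labels": list(labels), "n_per_class": n_per_class,
             "n_resampled": n_resampled, "l_i": fit.l_i, "seed": seed}
    return df, truth


def write_truth(truth: dict, path) -> None:
    """Dump a ground-truth record as JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
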