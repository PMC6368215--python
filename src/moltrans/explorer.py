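"""Exploration of the continuous descriptor space.

A trained model's latent space can be navigated: shift a molecule's latent
along a direction (a principal component of a reference set, or a random
unit vector), decode each shifted point back to a SMILES with the beam
search's validity fallback, and quantify how latent-space distance relates
to chemical distance. Per step the module records the mean Euclidean shift,
the mean Tanimoto distance between circular count fingerprints of the
decoded and starting molecules, and the valid-SMILES rates taking the top
1, 2 and 3 beam outputs into account (rate_1 <= rate_2 <= rate_3 by
construction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors
from scipy import stats

from . import inference
from .benchmarks import ecfc4_counts, tanimoto_counts
from .chem_prep import MoleculeRecord
from .seq2seq import Checkpoint


def principal_directions(latent_matrix: np.ndarray, n_components: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Principal axes of a latent reference set.

    Returns (directions (n_components x D), explained variances). Directions
    are orthonormal with a fixed sign convention: the largest-magnitude
    component of each direction is positive.
    """
    X = np.asarray(latent_matrix, dtype=np.float64)
    if X.shape[0] < n_components:
        raise ValueError("need at least n_components rows")
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / max(1, X.shape[0] - 1)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if n_components > rank:
        raise ValueError(f"n_components {n_components} exceeds rank {rank}")
    dirs = vt[:n_components]
    for i in range(dirs.shape[0]):
        j = int(np.argmax(np.abs(dirs[i])))
        if dirs[i, j] < 0:
            dirs[i] = -dirs[i]
    return dirs, var[:n_components]


def shift_trajectory(start: np.ndarray, direction: np.ndarray,
                     step_size: float, n_steps_each_way: int) -> np.ndarray:
    """Latents at steps -n..n: start + k * step_size * direction."""
    direction = np.asarray(direction, dtype=np.float64)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    ks = np.arange(-n_steps_each_way, n_steps_each_way + 1)
    return np.asarray(start)[None, :] + ks[:, None] * step_size * direction


def mean_nn_distance(latents: np.ndarray, sample: int = 200,
                     seed: int = 0) -> float:
    """Mean nearest-neighbour Euclidean distance of a latent set (the
    default exploration step size, so trajectories leave the data manifold
    gradually)."""
    rng = np.random.default_rng(seed)
    n = latents.shape[0]
    idx = rng.choice(n, size=min(sample, n), replace=False)
    d = np.linalg.norm(latents[idx, None, :] - latents[None, :, :], axis=2)
    d[np.arange(len(idx)), idx] = np.inf
    return float(d.min(axis=1).mean())


@dataclass
class ExplorationStepStats:
    """Aggregated per-step exploration statistics."""

    step_index: int
    d_euclidean: float
    d_tanimoto: float
    rate_1: float
    rate_2: float
    rate_3: float
    n: int


def _random_unit_directions(rng: np.random.Generator, R: int,
                            dim: int) -> np.ndarray:
    v = rng.normal(size=(R, dim))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def explore(checkpoint: Checkpoint, starts: Sequence[MoleculeRecord],
            n_directions: int, n_steps_each_way: int, step_size: float,
            seed: int = 0, width: int = 3, max_len: int = 80
            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random-direction walks around start molecules.

    For every (start, direction, step) the shifted latent is decoded with a
    beam of ``width``; the rank of the first hypothesis that parses as a
    valid molecule (1-based) defines the validity rates, and the circular
    count-fingerprint Tanimoto distance of that decode to its start defines
    the chemical distance. Returns (per-step stats table, per-decode log);
    the stats are exact aggregations of the log.
    """
    rng = np.random.default_rng(seed)
    lat = inference.encode_records(starts, checkpoint)
    dirs = _random_unit_directions(rng, n_directions, lat.shape[1])
    start_fps = [ecfc4_counts(r.mol()) for r in starts]
    rows = []
    for si, rec in enumerate(starts):
        for di in range(n_directions):
            traj = shift_trajectory(lat[si], dirs[di], step_size,
                                    n_steps_each_way)
            for off, k in enumerate(range(-n_steps_each_way,
                                          n_steps_each_way + 1)):
                smi, rank = inference.decode_latent(
                    traj[off], checkpoint, k=width, width=width,
                    max_len=max_len)
                d_tan = np.nan
                if smi is not None:
                    mol = Chem.MolFromSmiles(smi)
                    d_tan = 1.0 - tanimoto_counts(start_fps[si],
                                                  ecfc4_counts(mol))
                rows.append({"start": rec.id, "direction": di, "step": k,
                             "d_euclidean": abs(k) * step_size,
                             "rank": rank if rank is not None else 0,
                             "smiles": smi, "d_tanimoto": d_tan})
    log = pd.DataFrame(rows)
    stats_rows = []
    for k, grp in log.groupby("step"):
        ranks = grp["rank"].to_numpy()
        stats_rows.append(ExplorationStepStats(
            step_index=int(k),
            d_euclidean=float(grp["d_euclidean"].mean()),
            d_tanimoto=float(grp["d_tanimoto"].mean()),
            rate_1=float((ranks == 1).mean()),
            rate_2=float(((ranks >= 1) & (ranks <= 2)).mean()),
            rate_3=float(((ranks >= 1) & (ranks <= 3)).mean()),
            n=len(grp)))
    table = pd.DataFrame([vars(s) for s in stats_rows]).sort_values(
        "step_index").reset_index(drop=True)
    return table, log


_PROPERTY_FNS = {
    "mw": Descriptors.MolWt,
    "logp": Crippen.MolLogP,
}


def axis_property_correlation(checkpoint: Checkpoint,
                              starts: Sequence[MoleculeRecord],
                              direction: np.ndarray, n_steps_each_way: int,
                              step_size: float, property: str = "mw",
                              width: int = 3, max_len: int = 80
                              ) -> tuple[float, float, int]:
    """Mean Spearman correlation between step index and a decoded property.

    Per start molecule, the latent is shifted along ``direction`` over steps
    -n..n, each point decoded (validity fallback, failures dropped) and the
    chosen property (molecular weight or logP) computed on the decoded
    molecule. Trajectories with < 3 successful decodes or constant property
    are dropped with a warning. Returns (mean rho, combined p, trajectories
    used); the combined p is a two-sided one-sample Wilcoxon of the
    per-trajectory rho values against zero.
    """
    prop_fn = _PROPERTY_FNS[property]
    lat = inference.encode_records(starts, checkpoint)
    rhos = []
    for si in range(len(starts)):
        traj = shift_trajectory(lat[si], direction, step_size,
                                n_steps_each_way)
        steps, values = [], []
        for off, k in enumerate(range(-n_steps_each_way,
                                      n_steps_each_way + 1)):
            smi, _ = inference.decode_latent(traj[off], checkpoint, k=width,
                                             width=width, max_len=max_len)
            if smi is None:
                continue
            steps.append(k)
            values.append(prop_fn(Chem.MolFromSmiles(smi)))
        if len(steps) < 3 or np.std(values) < 1e-12:
            warnings.warn(f"trajectory {si} dropped (too few decodes or "
                          "constant property)")
            continue
        rho = stats.spearmanr(steps, values).statistic
        if np.isfinite(rho):
            rhos.append(float(rho))
    if not rhos:
        raise ValueError("no usable trajectories")
    if len(rhos) >= 5 and np.std(rhos) > 0:
        p = float(stats.wilcoxon(rhos, alternative="two-sided").pvalue)
    else:
        p = float("nan")
    return float(np.mean(rhos)), p, len(rhos)
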