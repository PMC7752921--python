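"""Synthetic populations emulating a multi-site brain-age study.

The generator produces per-subject ages from a truncated two-component normal
mixture (default: means 30 and 70 years, SDs 10, weights 0.55/0.45 on
[17, 90] — a bimodal adult distribution with few middle-aged subjects),
region-mean grey- and white-matter density features that depend linearly on
age with region-specific signed slopes plus noise, small additive per-site
feature offsets, balanced +1/-1 gender, and near-equal site assignment so the
whole age range is sampled at every site. Defaults mirror a 116-region,
17-site study with a 4:1 train/validation split.

Also provided: decoder-distortion scenarios (shrinkage towards the mean,
truncation, additive noise) for studying when distribution-matching
post-processing helps, and toy NIfTI volumes with known region means for
testing feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .data import Dataset

__all__ = [
    "PopulationConfig",
    "generate_population",
    "split_train_validation",
    "distort_predictions",
    "generate_toy_volumes",
]

#: Default age mixture: (mean, sd, weight) per component, years.
DEFAULT_AGE_MIXTURE = ((30.0, 10.0, 0.55), (70.0, 10.0, 0.45))


@dataclass
class PopulationConfig:
    """Parameters of the synthetic population.

    ``effect_scale`` is the magnitude scale of the per-region age slopes in
    density units per year (default 0.003: roughly a 0.2 density change over
    the adult age range); ``noise_sd`` is the per-feature observation noise
    and ``site_effect_sd`` the SD of the additive per-site feature offsets,
    both in density units.
    """

    n_subjects: int
    n_regions: int = 116
    n_sites: int = 17
    age_mixture: tuple = DEFAULT_AGE_MIXTURE
    age_range: tuple = (17.0, 90.0)
    effect_scale: float = 0.003
    noise_sd: float = 0.02
    site_effect_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        weights = [w for _, _, w in self.age_mixture]
        if any(w < 0 for w in weights) or not np.isclose(sum(weights), 1.0):
            raise ValueError(
                "age_mixture weights must be non-negative and sum to 1")
        if any(sd <= 0 for _, sd, _ in self.age_mixture):
            raise ValueError("age_mixture component SDs must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range lower bound must be below upper bound")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.site_effect_sd < 0:
            raise ValueError("site_effect_sd must be >= 0")


def _sample_truncated_mixture(rng: np.random.Generator, n: int,
                              mixture, age_range) -> np.ndarray:
    means = np.array([m for m, _, _ in mixture])
    sds = np.array([s for _, s, _ in mixture])
    weights = np.array([w for _, _, w in mixture])
    lo, hi = age_range
    component = rng.choice(len(mixture), size=n, p=weights)
    ages = rng.normal(means[component], sds[component])
    # redraw out-of-range values from their own component (truncation)
    bad = (ages < lo) | (ages > hi)
    while np.any(bad):
        ages[bad] = rng.normal(means[component[bad]], sds[component[bad]])
        bad = (ages < lo) | (ages > hi)
    return ages


def generate_population(config: PopulationConfig) -> Dataset:
    """Draw a synthetic multi-site population; deterministic given the seed.

    The generating parameters (slopes, intercepts, site offsets) are stored
    in ``Dataset.attrs["truth"]`` so recovery can be verified.
    """
    rng = np.random.default_rng(config.seed)
    n, R, S = config.n_subjects, config.n_regions, config.n_sites

    ages = _sample_truncated_mixture(rng, n, config.age_mixture,
                                     config.age_range)
    # balanced gender, random assignment
    gender = np.where(rng.permutation(n) % 2 == 0, 1.0, -1.0)
    # round-robin sites after a random shuffle: near-equal counts, age
    # independent of site
    site = rng.permutation(np.arange(n) % S)
    site_block = np.zeros((n, S))
    site_block[np.arange(n), site] = 1.0

    n_feat = 2 * R
    # region-specific signed slopes; GM intercepts above WM as in tissue maps
    slopes = (config.effect_scale * rng.uniform(0.3, 1.0, n_feat)
              * rng.choice([-1.0, 1.0], n_feat))
    intercepts = np.concatenate([rng.uniform(0.45, 0.65, R),
                                 rng.uniform(0.35, 0.55, R)])
    site_offsets = rng.normal(0.0, config.site_effect_sd, (S, n_feat))
    features = (intercepts[None, :] + ages[:, None] * slopes[None, :]
                + site_offsets[site]
                + rng.normal(0.0, config.noise_sd, (n, n_feat)))

    design = np.hstack([features, site_block, gender[:, None]])
    roles = np.asarray(["gm_region"] * R + ["wm_region"] * R
                       + ["site"] * S + ["gender"], dtype=object)
    subject_ids = np.asarray([f"sub-{i + 1:05d}" for i in range(n)],
                             dtype=object)
    truth = {"slopes": slopes, "intercepts": intercepts,
             "site_offsets": site_offsets, "site": site}
    return Dataset(ages=ages, design=design, column_roles=roles,
                   subject_ids=subject_ids, attrs={"truth": truth,
                                                   "config": config})


def split_train_validation(data: Dataset, ratio: float = 4.0, seed: int = 0,
                           match_age: bool = False) -> tuple[Dataset, Dataset]:
    """Disjoint train/validation split with ratio ``ratio``:1.

    With ``match_age`` the split is stratified on age deciles so the two
    empirical age distributions are matched.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    n = data.n
    n_train = int(round(n * ratio / (1.0 + ratio)))
    if n_train < 1 or n - n_train < 1:
        raise ValueError(
            f"ratio {ratio}:1 leaves an empty split for n = {n}")
    idx = np.arange(n)
    strata = None
    if match_age:
        strata = pd.qcut(data.ages, q=10, labels=False, duplicates="drop")
    train_idx, val_idx = train_test_split(
        idx, train_size=n_train, random_state=seed, stratify=strata)
    return data.subset(np.sort(train_idx)), data.subset(np.sort(val_idx))


def distort_predictions(y_true, mode: str, params: dict | None = None,
                        seed: int = 0) -> np.ndarray:
    """Turn true targets into distorted pseudo-predictions.

    Modes emulate characteristic decoder pathologies:

    - ``"shrink"``: y_hat = mean(y) + factor * (y - mean(y)) + noise —
      compressed range (extreme ages not predicted); params ``factor`` in
      (0, 1] and optional ``noise_sd`` >= 0. Ranks are preserved when
      ``noise_sd`` is 0.
    - ``"truncate"``: clip to ``[lower, upper]`` — saturating predictions.
    - ``"noise"``: y + Gaussian noise with ``sd``.
    """
    y = np.asarray(y_true, dtype=float).ravel()
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if mode == "shrink":
        factor = params.get("factor", 1.0)
        noise_sd = params.get("noise_sd", 0.0)
        if not 0.0 <= factor <= 1.0:
            raise ValueError("shrink factor must lie in [0, 1]")
        if noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if factor == 1.0:  # exact identity, no roundoff through the mean
            out = y.copy()
        else:
            out = y.mean() + factor * (y - y.mean())
        if noise_sd > 0:
            out = out + rng.normal(0.0, noise_sd, y.shape)
        return out
    if mode == "truncate":
        lower, upper = params["lower"], params["upper"]
        if not lower <= upper:
            raise ValueError("truncation bounds must be ordered")
        return np.clip(y, lower, upper)
    if mode == "noise":
        sd = params.get("sd", 1.0)
        if sd < 0:
            raise ValueError("noise sd must be >= 0")
        return y + rng.normal(0.0, sd, y.shape)
    raise ValueError(f"unknown distortion mode {mode!r}")


def generate_toy_volumes(grid: tuple[int, int, int], n_regions: int,
                         seed: int = 0, *, gm_values=None, wm_values=None,
                         affine=None):
    """Toy atlas + tissue volumes with exactly known region means.

    The first axis is partitioned into ``n_regions`` slabs labelled 1..R with
    the remainder left as background 0. When per-region constants
    ``gm_values``/``wm_values`` are given, tissue voxels are constant within
    each region (region means equal the constants exactly); otherwise voxel
    values are drawn uniformly at random. Returns nibabel images
    (label, GM, WM) with an identity affine (1 mm isotropic, RAS) unless
    ``affine`` is supplied.
    """
    grid = tuple(int(g) for g in grid)
    if len(grid) != 3 or any(g < 1 for g in grid):
        raise ValueError("grid must be three positive integers")
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    slab = grid[0] // (n_regions + 1)
    if slab < 1:
        raise ValueError(
            f"grid first dimension {grid[0]} too small for {n_regions} "
            "regions plus background")
    rng = np.random.default_rng(seed)
    labels = np.zeros(grid, dtype=np.int16)
    for r in range(n_regions):
        labels[r * slab:(r + 1) * slab] = r + 1

    def tissue(values) -> np.ndarray:
        if values is None:
            return rng.random(grid)
        values = np.asarray(values, dtype=float)
        if values.shape != (n_regions,):
            raise ValueError("per-region values must have length n_regions")
        vol = rng.random(grid)  # background voxels: arbitrary
        for r in range(n_regions):
            vol[labels == r + 1] = values[r]
        return vol

    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    label_img = nib.Nifti1Image(labels, affine)
    gm_img = nib.Nifti1Image(tissue(gm_values), affine)
    wm_img = nib.Nifti1Image(tissue(wm_values), affine)
    return label_img, gm_img, wm_img
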