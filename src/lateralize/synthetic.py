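"""Synthetic resting-state cohorts with planted lateralized effects.

The generator emulates the statistical structure the downstream analysis
assumes — not anatomy. Each atlas region carries a shared latent signal that
is white noise band-pass filtered to 0.01-0.08 Hz, mixed into its voxels
together with voxel-specific band-limited noise and broadband measurement
noise. Group differences are planted three ways, mirroring the three feature
categories:

* ``alff_regions`` — multiply the region's band-limited amplitude for the
  target group (local amplitude effect);
* ``reho_regions`` — raise the within-region mixing weight toward 1 for the
  target group (neighbourhood-coherence effect);
* ``fc_pairs`` — blend a common latent into two regions' signals for the
  target group only, inducing inter-regional correlation ~= delta.

Confounds per subject: six motion columns (smooth random walks) plus mean
signals of the global/white-matter/CSF compartments; WM and CSF are
designated non-ROI slabs of the grid so nuisance regression can be exercised
end to end. Defaults follow the emulated acquisition: 135 retained volumes
at TR 2.5 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .images import BoldImage, Parcellation
from .voxel import bandpass

__all__ = [
    "EffectSpec",
    "CohortSpec",
    "make_atlas",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
    "strong_lateralized_effects",
]

# Baseline within-region mixing weight: fraction of a voxel's band-limited
# variance shared with the region latent when no ReHo effect is planted.
BASE_MIXING = 0.3


@dataclass
class EffectSpec:
    """Planted group differences; all effects apply to ``target_group`` only."""

    alff_regions: list[tuple[int, float]] = field(default_factory=list)
    reho_regions: list[tuple[int, float]] = field(default_factory=list)
    fc_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    target_group: str = "L"

    def __post_init__(self) -> None:
        if self.target_group not in ("L", "R"):
            raise ValueError("target_group must be 'L' or 'R'")
        for _, w in self.reho_regions:
            if not 0.0 <= w <= 1.0:
                raise ValueError("ReHo mixing weights must lie in [0, 1]")
        for _, _, d in self.fc_pairs:
            if not 0.0 <= d < 1.0:
                raise ValueError("fc coupling delta must lie in [0, 1) so |r| < 1")
        for _, f in self.alff_regions:
            if f <= 0:
                raise ValueError("ALFF amplitude factors must be positive")


@dataclass
class CohortSpec:
    """Study-condition description for one synthetic cohort."""

    n_left: int = 7
    n_right: int = 5
    grid: tuple[int, int, int] = (12, 12, 8)
    n_timepoints: int = 135
    tr: float = 2.5
    n_regions: int = 12
    effect: EffectSpec = field(default_factory=EffectSpec)
    noise_sd: float = 0.5
    band: tuple[float, float] = (0.01, 0.08)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_left < 1 or self.n_right < 1:
            raise ValueError("need at least one subject per group")
        if self.n_timepoints < 16:
            raise ValueError("need at least 16 timepoints")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_subjects(self) -> int:
        return self.n_left + self.n_right

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = list(self.grid)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "effect" in d and isinstance(d["effect"], dict):
            eff = dict(d["effect"])
            eff["alff_regions"] = [tuple(x) for x in eff.get("alff_regions", [])]
            eff["reho_regions"] = [tuple(x) for x in eff.get("reho_regions", [])]
            eff["fc_pairs"] = [tuple(x) for x in eff.get("fc_pairs", [])]
            d["effect"] = EffectSpec(**eff)
        d["grid"] = tuple(d.get("grid", (12, 12, 8)))
        d["band"] = tuple(d.get("band", (0.01, 0.08)))
        return cls(**d)

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _factor_triple(n: int) -> tuple[int, int, int]:
    """Factor n into (a, b, c), a*b*c == n, as close to a cube as possible."""
    best = (1, 1, n)
    best_score = n
    for a in range(1, int(round(n ** (1 / 3))) + 2):
        if n % a:
            continue
        m = n // a
        for b in range(a, int(np.sqrt(m)) + 1):
            if m % b:
                continue
            c = m // b
            score = c / a
            if score < best_score:
                best_score = score
                best = (a, b, c)
    return best


def make_atlas(grid: tuple[int, int, int], n_regions: int, seed: int = 0) -> Parcellation:
    """Toy parcellation: axis-aligned contiguous blocks plus WM/CSF slabs.

    The top z-slice is reserved and split into white-matter and CSF
    compartments; the remaining volume is tiled into ``n_regions`` contiguous
    blocks of near-equal size. Every region must receive at least 27 voxels
    (a full 3x3x3 ReHo neighbourhood), otherwise a sizing error is raised.
    The construction is deterministic; ``seed`` is accepted for interface
    symmetry with the simulators.
    """
    nx, ny, nz = grid
    if nz >= 3:
        brain_nz = nz - 1
    else:
        brain_nz = nz  # grid too thin for a nuisance slab; no WM/CSF
    if nx * ny * brain_nz < 27 * n_regions:
        raise ValueError(
            f"grid {grid} too small for {n_regions} regions of >= 27 voxels "
            f"({nx * ny * brain_nz} usable voxels < {27 * n_regions})"
        )
    a, b, c = _factor_triple(n_regions)
    # Assign the most splits to the largest axes.
    order = np.argsort([nx, ny, brain_nz])[::-1]
    splits = [1, 1, 1]
    for ax, s in zip(order, sorted([a, b, c], reverse=True)):
        splits[ax] = s
    dims = (nx, ny, brain_nz)
    bounds = [np.linspace(0, d, s + 1).round().astype(int) for d, s in zip(dims, splits)]

    labels = np.zeros(grid, dtype=int)
    label = 1
    for i in range(splits[0]):
        for j in range(splits[1]):
            for k in range(splits[2]):
                labels[bounds[0][i]:bounds[0][i + 1],
                       bounds[1][j]:bounds[1][j + 1],
                       bounds[2][k]:bounds[2][k + 1]] = label
                label += 1
    sizes = np.bincount(labels.ravel())[1:]
    if sizes.size != n_regions or (sizes < 27).any():
        raise ValueError(
            f"grid {grid} cannot host {n_regions} contiguous regions of >= 27 voxels"
        )

    wm_mask = np.zeros(grid, dtype=bool)
    csf_mask = np.zeros(grid, dtype=bool)
    if brain_nz < nz:
        wm_mask[: nx // 2, :, brain_nz:] = True
        csf_mask[nx // 2:, :, brain_nz:] = True
    return Parcellation(labels=labels, wm_mask=wm_mask, csf_mask=csf_mask)


def _bandlimited_noise(rng: np.random.Generator, shape: tuple, tr: float,
                       band: tuple[float, float]) -> np.ndarray:
    """White noise band-passed to the analysis band, unit variance per series."""
    raw = rng.standard_normal(shape)
    filt = bandpass(raw, band[0], band[1], tr)
    sd = filt.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return filt / sd


def _subject_seed(spec_seed: int, index: int) -> int:
    """Deterministic, well-separated per-subject seed stream."""
    ss = np.random.SeedSequence(entropy=spec_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_subject(spec: CohortSpec, label: str, subject_seed: int,
                     parcellation: Parcellation | None = None
                     ) -> tuple[BoldImage, pd.DataFrame]:
    """Simulate one subject's BOLD run and confound table.

    Returns the :class:`BoldImage` (masked to the atlas brain) and a
    confounds DataFrame with columns mot_tx..mot_rz, global, wm, csf.
    """
    if label not in ("L", "R"):
        raise ValueError("label must be 'L' or 'R'")
    parc = parcellation if parcellation is not None else make_atlas(spec.grid, spec.n_regions)
    rng = np.random.default_rng(subject_seed)
    T, tr, band = spec.n_timepoints, spec.tr, spec.band
    R = parc.n_regions
    eff = spec.effect
    on = label == eff.target_group

    latents = _bandlimited_noise(rng, (R, T), tr, band)
    # FC effects: blend a common latent into both named regions (target group).
    if on:
        for i, j, delta in eff.fc_pairs:
            common = _bandlimited_noise(rng, (T,), tr, band)
            for r in (i, j):
                idx = r - 1
                latents[idx] = np.sqrt(1 - delta) * latents[idx] + np.sqrt(delta) * common
    amp = np.ones(R)
    mixing = np.full(R, BASE_MIXING)
    if on:
        for r, factor in eff.alff_regions:
            amp[r - 1] *= factor
        for r, w in eff.reho_regions:
            mixing[r - 1] = w

    data = np.zeros(spec.grid + (T,))
    for idx, roi in enumerate(parc.region_ids):
        vox = parc.labels == roi
        n_vox = int(vox.sum())
        eps = _bandlimited_noise(rng, (n_vox, T), tr, band)
        sig = np.sqrt(mixing[idx]) * latents[idx] + np.sqrt(1 - mixing[idx]) * eps
        data[vox] = amp[idx] * sig

    # Nuisance compartments get their own latents.
    compartments = {}
    for name, mask in (("wm", parc.wm_mask), ("csf", parc.csf_mask)):
        if mask is not None and mask.any():
            lat = _bandlimited_noise(rng, (T,), tr, band)
            n_vox = int(mask.sum())
            eps = _bandlimited_noise(rng, (n_vox, T), tr, band)
            data[mask] = np.sqrt(0.5) * lat + np.sqrt(0.5) * eps
            compartments[name] = mask

    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(data.shape)

    bold = BoldImage(data, tr=tr, mask=parc.brain_mask)

    motion = np.cumsum(0.02 * rng.standard_normal((T, 6)), axis=0)
    conf = {f"mot_{ax}": motion[:, k]
            for k, ax in enumerate(["tx", "ty", "tz", "rx", "ry", "rz"])}
    conf["global"] = data[parc.brain_mask].mean(axis=0)
    for name in ("wm", "csf"):
        mask = compartments.get(name)
        conf[name] = data[mask].mean(axis=0) if mask is not None else np.zeros(T)
    confounds = pd.DataFrame(conf)
    return bold, confounds


def simulate_cohort(spec: CohortSpec
                    ) -> tuple[list[tuple[BoldImage, pd.DataFrame, str]], Parcellation]:
    """Simulate the whole cohort: n_left 'L' subjects then n_right 'R' subjects.

    Per-subject seeds derive deterministically from ``spec.seed`` so the
    cohort is reproducible while subjects stay independent.
    """
    parc = make_atlas(spec.grid, spec.n_regions, spec.seed)
    subjects = []
    labels = ["L"] * spec.n_left + ["R"] * spec.n_right
    for index, label in enumerate(labels):
        bold, conf = simulate_subject(spec, label, _subject_seed(spec.seed, index), parc)
        subjects.append((bold, conf, label))
    return subjects, parc


def strong_lateralized_effects(n_regions: int = 12) -> EffectSpec:
    """Default strong planted effects used by demos and power checks.

    One amplitude region (x2.0), one coherence region (mixing 0.9) and one
    coupled pair (delta 0.6), all carried by the left group.
    """
    if n_regions < 8:
        raise ValueError("strong effect preset expects at least 8 regions")
    return EffectSpec(
        alff_regions=[(3, 2.0)],
        reho_regions=[(5, 0.9)],
        fc_pairs=[(1, 7, 0.6)],
        target_group="L",
    )


def write_cohort(spec: CohortSpec, outdir) -> pd.DataFrame:
    """Write a cohort to disk: per-subject 4D NIfTI + confound TSVs, atlas
    NIfTI, subject table TSV and the cohort spec as YAML. Returns the table."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects, parc = simulate_cohort(spec)
    parc.save(outdir / "atlas.nii.gz")
    spec.save_yaml(outdir / "cohort.yaml")
    rows = []
    for i, (bold, conf, label) in enumerate(subjects):
        sid = f"sub-{i + 1:02d}"
        bold.save(outdir / f"{sid}_bold.nii.gz")
        conf.to_csv(outdir / f"{sid}_confounds.tsv", sep="\t", index=False)
        rows.append({"subject_id": sid, "label": label})
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    return table
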