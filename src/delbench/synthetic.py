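"""Synthetic DEL screening campaigns with known ground truth.

Every downstream stage (hit calling, ranking metrics, building-block
statistics, accessibility scoring) can be exercised end-to-end on data
from this module, with the planted truth returned alongside so recovery
is checkable.

The generative model:

* **Library** — a combinatorial chain of positions; fragment SMILES are
  drawn deterministically from a small alphabet of valid single- and
  double-attachment bodies.
* **Affinity** — additive over building blocks: each block carries a
  Gaussian background contribution, and one planted block per position
  carries an extra ``planted_effect``.  Block identity driving binding is
  exactly the premise under which P_bind/CP analysis is meaningful.
* **Screen** — read counts are Poisson.  Pre-selection rates are uniform;
  post-selection rates are proportional to ``exp(s * affinity)`` with the
  scale ``s`` calibrated so the strongest binder is enriched
  ``selection_depth``-fold over the average compound.
* **Docking** — scores follow a Gaussian copula against affinity with
  correlation ``rho`` (``rho = 1`` inverts the affinity ranking exactly,
  ``rho = 0`` is independent); a configurable fraction fails to dock.
  VHL values are the empirical CDF of a noisy monotone transform of the
  latent score.
* **Pocket** — a spherical shell of pseudo-atoms with one circular
  opening about +z.  Exposed poses aim their exit vector through the
  opening from the axis; with the default opening half-angle above 90°
  every wall atom lies strictly behind the vector, so B = 0 holds as a
  geometric identity.  Buried poses aim at the far wall inside the
  scoring cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm, rankdata

from .accessibility import ExitVector, PoseGeometry, ProteinAtoms
from .library import BuildingBlock, CompoundRecord, LibraryDefinition, enumerate_library
from .metrics import DockRecord
from .screen import ReadCountRecord

__all__ = ["SynthConfig", "ScreenTruth", "synth_library", "synth_screen", "synth_dock", "synth_pocket"]

_MAX_ENUMERATION = 10**6

# bodies with one open valence (chain ends) / two (chain middles)
_END_BODIES = ["C", "CC", "CO", "CN", "CCC", "CCO", "CCN", "C(C)C", "COC", "CNC"]
_MID_BODIES = ["C", "CC", "CO", "CN", "CCC", "COC", "CNC", "CCO", "CCN", "C(C)C"]


@dataclass
class SynthConfig:
    """Knobs of the synthetic campaign; defaults are the study conditions.

    cardinalities : per-position block counts (default 12 x 16 x 18,
        3,456 compounds — large enough for top-1,000 analyses, small
        enough to enumerate instantly).
    planted_effect : extra affinity (arbitrary units) of the one planted
        block per position, on top of N(0, background_sd) backgrounds.
    selection_depth : expected fold enrichment of the strongest binder
        relative to the average compound (read-rate ratio after/before).
    sequencing_depth : total reads per sample.
    rho : Gaussian-copula correlation between docking score and affinity.
    undocked_fraction : probability a compound fails to dock.
    buried_fraction : fraction of generated poses with a buried exit
        vector (deterministic count, round(f * n)).
    """

    cardinalities: tuple[int, ...] = (12, 16, 18)
    planted_effect: float = 3.0
    background_sd: float = 0.5
    selection_depth: float = 100.0
    sequencing_depth: int = 1_000_000
    rho: float = 0.8
    undocked_fraction: float = 0.0
    buried_fraction: float = 0.3
    shell_radius: float = 7.0
    opening_half_angle_deg: float = 95.0
    n_shell_points: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cardinalities or any(c < 1 for c in self.cardinalities):
            raise ValueError("cardinalities must all be >= 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if not 0.0 <= self.undocked_fraction < 1.0:
            raise ValueError("undocked_fraction must be in [0, 1)")
        if not 0.0 <= self.buried_fraction <= 1.0:
            raise ValueError("buried_fraction must be in [0, 1]")
        if self.selection_depth < 1.0:
            raise ValueError("selection_depth must be >= 1")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")
        if not 0.0 < self.opening_half_angle_deg < 180.0:
            raise ValueError("opening half-angle must be in (0, 180) degrees")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator for one named stream."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class ScreenTruth:
    """Planted ground truth emitted next to the synthetic screen."""

    affinity: np.ndarray  # per compound, enumeration order
    block_effects: list[np.ndarray]  # per position, per block
    planted_blocks: list[int]  # the strong block index per position
    depth_scale: float  # the calibrated exponent s


def _fragment(position: int, index: int, n_positions: int) -> str:
    if n_positions == 1:
        body = _END_BODIES[index % len(_END_BODIES)]
        return body + "C" * (index // len(_END_BODIES))
    pad_left = "C" * (index // len(_END_BODIES))
    if position == 0:
        body = _END_BODIES[index % len(_END_BODIES)]
        return body + pad_left + "[*:1]"
    if position == n_positions - 1:
        body = _END_BODIES[index % len(_END_BODIES)]
        return f"[*:{position}]" + pad_left + body
    body = _MID_BODIES[index % len(_MID_BODIES)]
    return f"[*:{position}]" + pad_left + body + f"[*:{position + 1}]"


def synth_library(
    cfg: SynthConfig, with_smiles: bool = True
) -> tuple[LibraryDefinition, list[CompoundRecord]]:
    """Deterministic chain-topology library plus its full enumeration."""
    size = int(np.prod(cfg.cardinalities))
    if size > _MAX_ENUMERATION:
        raise ValueError(
            f"library of {size} compounds exceeds the full-enumeration limit "
            f"{_MAX_ENUMERATION}; use count-only mode on a LibraryDefinition"
        )
    n_pos = len(cfg.cardinalities)
    blocks = [
        [
            BuildingBlock(p, i, _fragment(p, i, n_pos), label=f"synth-p{p}b{i}")
            for i in range(card)
        ]
        for p, card in enumerate(cfg.cardinalities)
    ]
    defn = LibraryDefinition(blocks=blocks, name="synthetic")
    records = list(enumerate_library(defn, with_smiles=with_smiles))
    return defn, records


def _block_effects(cfg: SynthConfig) -> tuple[list[np.ndarray], list[int]]:
    rng = cfg.rng(1)
    effects, planted = [], []
    for card in cfg.cardinalities:
        eff = rng.normal(0.0, cfg.background_sd, size=card)
        star = int(rng.integers(card))
        eff[star] += cfg.planted_effect
        effects.append(eff)
        planted.append(star)
    return effects, planted


def _depth_scale(affinity: np.ndarray, selection_depth: float) -> float:
    """Solve exp(s*a_max)/mean(exp(s*a)) = selection_depth for s >= 0."""
    a = affinity - affinity.max()  # stabilized; ratio is shift-invariant
    if selection_depth == 1.0 or np.allclose(a, 0.0):
        return 0.0
    # the ratio saturates at n / #maxima as s -> inf; clamp unreachable targets
    limit = len(a) / np.sum(a == 0.0)
    target = selection_depth
    if target >= 0.9 * limit:
        target = 0.9 * limit
        warnings.warn(
            f"selection_depth {selection_depth} unreachable for a library of "
            f"{len(a)} compounds; clamped to {target:.3g}"
        )

    def log_ratio(s: float) -> float:
        w = np.exp(s * a)
        return -np.log(w.mean()) - np.log(target)

    hi = 1.0
    while log_ratio(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("depth-scale calibration failed to bracket")
    return float(brentq(log_ratio, 0.0, hi, xtol=1e-12))


def synth_screen(
    cfg: SynthConfig, records: Sequence[CompoundRecord]
) -> tuple[list[ReadCountRecord], ScreenTruth]:
    """Poisson read counts before/after selection plus the planted truth."""
    effects, planted = _block_effects(cfg)
    bb = np.asarray([rec.bb_indices for rec in records], dtype=np.int64)
    affinity = np.zeros(len(records))
    for p in range(bb.shape[1]):
        affinity += effects[p][bb[:, p]]

    s = _depth_scale(affinity, cfg.selection_depth)
    w = np.exp(s * (affinity - affinity.max()))
    n = len(records)
    lam_before = np.full(n, cfg.sequencing_depth / n)
    lam_after = cfg.sequencing_depth * w / w.sum()

    rng = cfg.rng(2)
    before = rng.poisson(lam_before)
    after = rng.poisson(lam_after)
    total_before = max(int(before.sum()), 1)
    total_after = max(int(after.sum()), 1)
    out = [
        ReadCountRecord(
            compound_id=rec.compound_id,
            count_before=int(b),
            count_after=int(a),
            total_before=total_before,
            total_after=total_after,
        )
        for rec, b, a in zip(records, before, after)
    ]
    truth = ScreenTruth(
        affinity=affinity, block_effects=effects, planted_blocks=planted, depth_scale=s
    )
    return out, truth


def synth_dock(
    cfg: SynthConfig,
    records: Sequence[CompoundRecord],
    affinity: np.ndarray,
    with_vhl: bool = True,
) -> list[DockRecord]:
    """Docking deck with tunable score-affinity rank correlation.

    The latent score is ``-(rho * z + sqrt(1 - rho^2) * eps)`` where z is
    the normal score of the affinity rank — a Gaussian copula, so the
    achieved Spearman correlation is (6/pi)·asin(rho/2) with exact
    endpoints at rho = 0 and rho = 1.
    """
    affinity = np.asarray(affinity, dtype=float)
    n = len(records)
    if affinity.shape != (n,):
        raise ValueError("affinity must align with records")
    rng = cfg.rng(3)
    z = norm.ppf((rankdata(affinity, method="average") - 0.5) / n)
    eps = rng.standard_normal(n)
    latent = cfg.rho * z + np.sqrt(1.0 - cfg.rho**2) * eps
    score = -latent  # lower = better, like a docking energy
    undocked = rng.random(n) < cfg.undocked_fraction

    vhl = None
    if with_vhl:
        vhl_latent = latent + 0.5 * rng.standard_normal(n)
        vhl = (rankdata(vhl_latent, method="average") - 0.5) / n

    return [
        DockRecord(
            compound_id=rec.compound_id,
            score=None if undocked[i] else float(score[i]),
            docked=not undocked[i],
            vhl=float(vhl[i]) if vhl is not None else None,
        )
        for i, rec in enumerate(records)
    ]


def _shell_atoms(cfg: SynthConfig) -> np.ndarray:
    """Fibonacci-sphere shell with the polar cap above the opening removed."""
    n = cfg.n_shell_points
    k = np.arange(n)
    phi = np.arccos(1.0 - 2.0 * (k + 0.5) / n)  # polar angle from +z
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * k
    pts = cfg.shell_radius * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    keep = phi >= np.deg2rad(cfg.opening_half_angle_deg)
    pts = pts[keep]
    if not len(pts):
        raise ValueError("opening larger than the shell: no wall atoms remain")
    return pts


def synth_pocket(
    cfg: SynthConfig, n_poses: int
) -> tuple[ProteinAtoms, list[PoseGeometry], list[bool]]:
    """Toy pocket plus poses; returns ground-truth buried flags.

    Exactly ``round(buried_fraction * n_poses)`` poses are buried (exit
    vector aimed at the far wall); the rest aim through the opening.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    wall = _shell_atoms(cfg)
    protein = ProteinAtoms(coords=wall, elements=["C"] * len(wall))

    rng = cfg.rng(4)
    n_buried = int(round(cfg.buried_fraction * n_poses))
    buried_flags = np.zeros(n_poses, dtype=bool)
    buried_flags[:n_buried] = True
    rng.shuffle(buried_flags)

    poses: list[PoseGeometry] = []
    for k in range(n_poses):
        jitter = rng.uniform(-0.5, 0.5, size=2)
        azimuth = rng.uniform(0.0, 2 * np.pi)
        side = 0.8 * np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
        if buried_flags[k]:
            terminal = np.array([jitter[0], jitter[1], 2.0])
            direction = np.array([0.0, 0.0, -1.0])  # into the far wall
        else:
            terminal = np.array([jitter[0], jitter[1], 1.5])
            direction = np.array([0.0, 0.0, 1.0])  # through the opening
        base = terminal - 1.5 * direction
        extra = base + side
        coords = np.vstack([extra, base, terminal])
        poses.append(
            PoseGeometry(
                coords=coords,
                exit_vectors=[ExitVector(base_atom=1, terminal_atom=2)],
                pose_id=f"pose_{k}",
            )
        )
    return protein, poses, [bool(b) for b in buried_flags]
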