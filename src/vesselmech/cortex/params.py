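"""Parameters for the 2D actomyosin cortex model.

Units are micrometres, seconds and piconewtons throughout (2D stress in
pN/um).  The endothelial cell is approximated as a flat 2D rectangle of
8 um (horizontal = circumferential, x) by 30 um (vertical = longitudinal,
y, periodic).  A few anchored filaments (2 um long, about one fourth of
the vessel width, at most 1% of all filaments) seed bundle formation
either at the longitudinal membranes or along the vertical midline.

All numeric defaults are this package's own calibration, loosely in the
range of published coarse-grained actomyosin models, and every one of
them can be overridden from a config file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["SimParams", "default_params", "load_params", "save_params"]

MAX_SEGMENTS = 6
MAX_BEADS = MAX_SEGMENTS + 1


@dataclass(frozen=True)
class SimParams:
    # domain
    Lx: float = 8.0                 # um, circumferential
    Ly: float = 30.0                # um, longitudinal (periodic)
    boundary_mode: str = "fixed_walls"   # or "deformable_membrane"

    # counts
    n_filaments: int = 400
    n_motors: int = 800
    n_crosslinkers: int = 800
    n_anchored: int = 4
    anchoring_mode: str = "longitudinal_membrane"  # "midline" | "none"
    anchored_length: float = 2.0    # um, ~one fourth of the vessel width
    anchored_band: float = 3.0      # um, y-extent of the anchored band

    # filament mechanics
    segment_rest_length: float = 0.5     # um
    stretch_stiffness: float = 20.0      # pN/um
    persistence_length: float = 10.0     # um -> bending rigidity kT*Lp
    min_segments: int = 2
    max_segments: int = MAX_SEGMENTS

    # motor properties
    motor_on_rate: float = 5.0           # 1/s within capture radius
    motor_off_rate: float = 0.5          # 1/s
    motor_speed: float = 0.2             # um/s toward the plus end, unloaded
    motor_stall_force: float = 4.0       # pN
    link_stiffness: float = 20.0         # pN/um
    link_rest_length: float = 0.1        # um
    capture_radius: float = 0.1          # um
    motor_end_dwell: bool = False        # hold at the plus end until unbinding
    detachment_force: float = 4.0        # pN, Bell slip-bond unbinding scale

    # crosslinker properties
    xl_on_rate: float = 5.0
    xl_off_rate: float = 0.1
    xl_align_stiffness: float = 0.05     # pN*um, nematic bundling torque
    xl_protect_heads: int = 0            # >=N bound heads exempt a filament
                                         # from turnover (0 = disabled)

    # kinetics
    turnover_rate: float = 1.0 / 30.0    # 1/s whole-filament replacement (free only)
    poly_rate: float = 0.1               # segments/s at the plus end
    depoly_rate: float = 0.1             # segments/s at the minus end

    # membrane (deformable mode)
    membrane_spacing: float = 0.5        # um between beads
    membrane_stretch: float = 20.0       # pN/um
    membrane_bending: float = 1.0        # pN*um^2
    foundation_stiffness: float = 0.05   # pN/um lateral spring to rest x
    membrane_drag: float = 10.0          # pN*s/um per bead
    wall_stiffness: float = 20.0         # pN/um confinement of free beads

    # integration
    dt: float = 0.005                    # s, explicit overdamped Euler
    drag: float = 0.5                    # pN*s/um per filament bead
    kT: float = 0.0042                   # pN*um, thermal energy
    thermal_noise: bool = True

    seed: int = 0

    def __post_init__(self):
        if self.Lx <= 0 or self.Ly <= 0:
            raise ValueError("domain dimensions must be positive")
        if self.boundary_mode not in ("fixed_walls", "deformable_membrane"):
            raise ValueError("unknown boundary_mode")
        if self.anchoring_mode not in ("longitudinal_membrane", "midline", "none"):
            raise ValueError("unknown anchoring_mode")
        if self.anchoring_mode != "none" and self.n_anchored > 0:
            if self.n_anchored > 0.01 * self.n_filaments:
                raise ValueError(
                    "anchored filaments must be at most 1% of all filaments"
                )
        if self.max_segments > MAX_SEGMENTS:
            raise ValueError(f"max_segments capped at {MAX_SEGMENTS}")
        if not self.min_segments >= 1:
            raise ValueError("min_segments must be >= 1")
        if self.dt >= self.stability_bound():
            raise ValueError(
                f"unstable: dt={self.dt} exceeds stability bound "
                f"{self.stability_bound():.4g} = drag/(4*k_max)"
            )

    def k_max(self) -> float:
        return max(self.stretch_stiffness, self.link_stiffness,
                   self.wall_stiffness)

    def stability_bound(self) -> float:
        """Explicit-Euler stability bound dt < drag/(4*k_max) for the
        stiffest spring acting on a filament bead."""
        return self.drag / (4.0 * self.k_max())

    @property
    def bending_rigidity(self) -> float:
        """kappa = kT * Lp, pN*um^2."""
        return self.kT * self.persistence_length

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


def default_params(preset: str = "paper_like", **overrides) -> SimParams:
    """Named parameter presets.

    ``paper_like``: full counts (400 filaments, 800 motors, 800
    crosslinkers, 4 anchored).  ``reduced_test``: identical physics
    constants with counts halved (200/400/400, 2 anchored — one per side,
    preserving the bridging geometry) for fast runs.
    """
    if preset == "paper_like":
        p = SimParams()
    elif preset == "reduced_test":
        p = SimParams(n_filaments=200, n_motors=400, n_crosslinkers=400,
                      n_anchored=2)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return p.replace(**overrides) if overrides else p


def save_params(params: SimParams, path: str | Path) -> None:
    """Echo every parameter (and the seed) to a JSON or YAML file."""
    path = Path(path)
    data = dataclasses.asdict(params)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_params(path: str | Path) -> SimParams:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(path.read_text())
    else:
        data = json.loads(path.read_text())
    known = {f.name for f in dataclasses.fields(SimParams)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimParams(**data)
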