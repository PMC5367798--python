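"""Run configuration for a docking calculation.

Defaults follow the regimes that work well for the tensor-train
optimizer on fine grids: moderate maximal TT-rank with a finer grid, 15
outer iterations, a 10-angstrom docking cube for the ligand center and a
1-angstrom cube (i.e. +/- 0.5 angstrom) per moveable receptor atom.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field


@dataclass
class DockingConfig:
    #: docking-cube center (angstrom); None = geometric center of the
    #: input (native) ligand pose
    cube_center: tuple[float, float, float] | None = None
    #: edge of the axis-aligned docking cube for the ligand center (angstrom)
    cube_edge: float = 10.0
    #: edge of each moveable atom's own cube (angstrom); atoms stay within
    #: +/- atom_cube_edge/2 of their crystallographic position
    atom_cube_edge: float = 1.0
    #: maximal TT-rank of the cross interpolation
    r_max: int = 8
    #: grid bits: every dimension is discretized into n = 2**m nodes
    m: int = 12
    #: outer iterations of the TT magnitude-maximization loop
    iterations: int = 15
    #: random seed (drives interpolation-set seeding; the run is
    #: deterministic given the seed)
    seed: int = 0
    #: moveable-layer thickness for marking moveable receptor atoms (angstrom)
    mlt: float = 3.0
    #: energy-evaluation budget of the rough in-loop simplex refinement
    refine_budget: int = 200
    #: how many harvested points are locally refined per iteration
    #: (None = r_max)
    refine_top: int | None = None
    #: cap on each unfolding's interpolation set (None = 2 * r_max)
    set_cap: int | None = None
    #: ligand-RMSD threshold of the pre-optimization dedup sweep (angstrom)
    sorter_threshold: float = 0.1
    #: symmetry-RMSD threshold of the post-optimization dedup sweep (angstrom)
    unique_threshold: float = 0.1

    @property
    def n(self) -> int:
        return 2 ** self.m

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def digest(self) -> int:
        """Stable 32-bit hash of the configuration (store header)."""
        h = hashlib.sha256(self.to_json().encode()).digest()
        return int.from_bytes(h[:4], "little")
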