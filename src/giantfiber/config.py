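"""Run configuration: YAML serialization and master-seed fan-out.

A :class:`RunConfig` gathers every tunable of the circuit model, the
stimulus protocols, the occupancy sweep and the synthetic-data stage, and
round-trips to a flat YAML mapping so a run is fully described by one text
file plus one master seed. Stage seeds are derived from the master seed
with ``numpy.random.SeedSequence(master_seed).generate_state`` in a fixed
stage order, so any stage can be re-run independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

from .biophysics import MembraneParams
from .circuit import CircuitParams, DEFAULT_GENOTYPE_OCCUPANCIES
from .synapse import ChemSynapseParams, GapMapParams

__all__ = ["RunConfig", "stage_seed", "STAGE_ORDER"]

# Fixed fan-out order for per-stage child seeds.
STAGE_ORDER = ("simulate", "sweep", "generate", "compare", "calibrate")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic child seed for a named pipeline stage."""
    if stage not in STAGE_ORDER:
        raise ValueError(f"unknown stage {stage!r}; one of {STAGE_ORDER}")
    state = np.random.SeedSequence(master_seed).generate_state(len(STAGE_ORDER))
    return int(state[STAGE_ORDER.index(stage)])


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a model-exploration / comparison run."""

    # membrane (shared by all four compartments)
    c_m: float = 1.0
    g_na: float = 50.0
    g_k: float = 20.0
    g_leak: float = 2.0
    # circuit
    g_axial: float = 6.0
    g_syn: float = 0.1
    v_syn: float = 0.0
    tau_rise: float = 0.1
    tau_decay: float = 3.0
    l_min: float = 0.01
    l_max: float = 2.0
    k_sig: float = 1.25
    x0: float = 6.2
    p_sat: float = 10.0
    occupancy: float = 9.04
    chem_enabled: bool = True
    rectify_gap: bool = False
    # protocol
    pulse_amplitude: float = 300.0
    pulse_width: float = 1.0
    noise_sd: float = 1.0
    dt: float = 0.01
    n_reps: int = 10
    occupancy_list: tuple[float, ...] = DEFAULT_GENOTYPE_OCCUPANCIES
    # bookkeeping
    master_seed: int = 0
    out_dir: str = "runs"
    verbosity: int = 1

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    # -- model-object construction ---------------------------------------
    def membrane_params(self) -> MembraneParams:
        return MembraneParams(c_m=self.c_m, g_na=self.g_na, g_k=self.g_k,
                              g_leak=self.g_leak)

    def circuit_params(self) -> CircuitParams:
        mem = self.membrane_params()
        return CircuitParams(
            membrane=(mem, mem, mem, mem),
            g_axial=self.g_axial,
            chem=ChemSynapseParams(g_syn=self.g_syn, v_syn=self.v_syn,
                                   tau_rise=self.tau_rise,
                                   tau_decay=self.tau_decay),
            gap_map=GapMapParams(l_min=self.l_min, l_max=self.l_max,
                                 k_sig=self.k_sig, x0=self.x0,
                                 p_sat=self.p_sat),
            occupancy=self.occupancy,
            chem_enabled=self.chem_enabled,
            rectify_gap=self.rectify_gap,
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["occupancy_list"] = list(self.occupancy_list)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "occupancy_list" in d:
            d = dict(d, occupancy_list=tuple(float(p)
                                             for p in d["occupancy_list"]))
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for run logs."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
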