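"""YAML run-configuration schema.

A morph run is described by one YAML document::

    flexibility:
      - {chain: A, first: 9, last: 10, level: residue-torsions}
    welds:
      - [{chain: A}, {chain: B}]
    spheres:
      - {center: {chain: A, residue: 9, atom: CA}, radius: 5.0, stiffness: 100.0}
      - {center: {point: [1.0, 2.0, 3.0]}, radius: 4.0}
    physics_zone_radius: 10.0
    chain_pairs: [[A, A]]
    alignment_chains: [[A, A]]
    force_constant: 30.0
    convergence: {threshold: 50.0, window: 5}
    report_interval: 5
    max_steps: 20000
    atom_policy: representative

Only ``chain_pairs`` is required; everything else has the engine's
defaults.  Selections may also be given on the command line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import yaml

from .flexibility import CollisionSphere, FlexibleSelection, MobilitySpec, Segment
from .morph_engine import MorphConfig

__all__ = ["RunConfig", "load_run_config"]


@dataclass
class RunConfig:
    mobility: MobilitySpec
    morph: MorphConfig
    chain_pairs: List[Tuple[str, str]]
    alignment_chain_pairs: Optional[List[Tuple[str, str]]] = None


def _segment(d: dict) -> Segment:
    return Segment(chain_id=d["chain"], first=d.get("first"), last=d.get("last"))


def _sphere(d: dict) -> CollisionSphere:
    center = d["center"]
    kwargs = dict(radius=float(d["radius"]),
                  stiffness=float(d.get("stiffness", 100.0)))
    if "point" in center:
        kwargs["center_point"] = [float(v) for v in center["point"]]
    else:
        kwargs["center_atom"] = (center["chain"], int(center["residue"]),
                                 center["atom"])
    return CollisionSphere(**kwargs)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}

    selections = []
    for item in doc.get("flexibility", []):
        selections.append(FlexibleSelection(
            chain_id=item["chain"], first=int(item["first"]),
            last=int(item["last"]),
            level=item.get("level", "residue-torsions"),
            bonds=[tuple(b) for b in item.get("bonds", [])]))
    welds = [(_segment(a), _segment(b)) for a, b in doc.get("welds", [])]
    spheres = [_sphere(d) for d in doc.get("spheres", [])]
    mobility = MobilitySpec(
        flexible_selections=selections, welds=welds,
        collision_spheres=spheres,
        physics_zone_radius=float(doc.get("physics_zone_radius", 10.0)))

    conv = doc.get("convergence", {})
    morph = MorphConfig(
        report_interval=int(doc.get("report_interval", 5)),
        convergence_threshold=float(conv.get("threshold", 50.0)),
        convergence_window=int(conv.get("window", 5)),
        max_steps=int(doc.get("max_steps", 20000)),
        max_wall_time=doc.get("max_wall_time"),
        force_constant=float(doc.get("force_constant", 30.0)),
        atom_policy=doc.get("atom_policy", "representative"),
        seed=int(doc.get("seed", 0)))

    chain_pairs = [tuple(p) for p in doc.get("chain_pairs", [])]
    if not chain_pairs:
        raise ValueError(f"{path}: chain_pairs is required")
    alignment = doc.get("alignment_chains")
    alignment_pairs = [tuple(p) for p in alignment] if alignment else None
    return RunConfig(mobility=mobility, morph=morph,
                     chain_pairs=chain_pairs,
                     alignment_chain_pairs=alignment_pairs)
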