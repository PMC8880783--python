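#!/usr/bin/env python
"""Rigid-body rotation recovery between conformational states.

Found: a constructed 24 degree swing of the C1-bearing chain is recovered
exactly from noiseless coordinates; with Gaussian coordinate noise the
recovery error on the multi-cluster A-chain domain (36 atoms spread over
tens of Å) stays well under half a degree at 0.2 Å noise.
"""

import json
from dataclasses import replace
from pathlib import Path

import numpy as np

import cofnet as cn

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pb = cn.make_hydabcsl_fixture("PB", seed=SEED)
    axis = np.array([0.2, 0.9, -0.4])
    axis = axis / np.linalg.norm(axis)
    rotated = cn.make_rotated_state(pb, "chain C", 24.0, axis, pivot=(0, 0, 0))
    motion = cn.domain_rotation(pb, rotated, core="not chain C", domain="chain C")
    print(f"noiseless recovery: {motion.angle:.6f} degrees "
          f"(axis {np.round(motion.axis, 3)})")

    # noise sweep on the larger A-chain domain (five clusters, 36 atoms)
    rotated_a = cn.make_rotated_state(pb, "chain A", 24.0, axis, pivot=(0, 0, 0))
    rng = np.random.default_rng(SEED)
    rows = []
    for sigma in (0.0, 0.05, 0.1, 0.2, 0.4):
        noisy = cn.Structure(atoms=[
            replace(a, position=a.position + rng.normal(scale=sigma, size=3))
            for a in rotated_a.atoms])
        m = cn.domain_rotation(pb, noisy, "not chain A", "chain A")
        rows.append({"sigma_A": sigma, "angle_deg": round(m.angle, 4),
                     "abs_error_deg": round(abs(m.angle - 24.0), 4)})
        print(f"sigma {sigma:4.2f} Å -> {m.angle:7.3f} deg "
              f"(error {abs(m.angle - 24.0):.3f})")
    (OUT / "rotation_recovery.json").write_text(json.dumps(rows, indent=2))


if __name__ == "__main__":
    main()
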