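#!/usr/bin/env python
"""Sweep (KN, KD) and map steady-state Delta and signaling speed at t=10.

KN is log-spaced over [0.1, 10] (the experimentally plausible range) and KD
linear over [0.1, 2], bracketing the fitted healthy range (0.2-0.3) and the
elevated-KD injury regime.  The headline model prediction — signaling speed
is non-decreasing in KD at every KN — is checked exhaustively on the grid.
"""

from pathlib import Path

import numpy as np

from notchdyn.circuit import phase_map
from notchdyn.io import write_manifest, write_phase_map

OUT = Path(__file__).resolve().parents[1] / "results" / "phase_maps"

KN_GRID = np.logspace(-1, 1, 15)
KD_GRID = np.linspace(0.1, 2.0, 12)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    delta_map = phase_map(KN_GRID, KD_GRID, metric="steady_state_delta")
    speed_map = phase_map(KN_GRID, KD_GRID, metric="signaling_speed")
    write_phase_map(delta_map, OUT / "steady_state_delta.csv")
    write_phase_map(speed_map, OUT / "signaling_speed.csv")

    monotone = np.all(np.diff(speed_map.values, axis=1) >= -1e-9)
    print(f"grid: {KN_GRID.size} KN x {KD_GRID.size} KD values")
    print(f"steady-state Delta range: {delta_map.values.min():.3f} - {delta_map.values.max():.3f}")
    print(f"signaling speed range: {speed_map.values.min():.3f} - {speed_map.values.max():.3f}")
    print(f"speed non-decreasing in KD at every KN: {monotone}")
    write_manifest(OUT / "manifest.json", command="02_phase_maps",
                   kn_grid=list(KN_GRID), kd_grid=list(KD_GRID))


if __name__ == "__main__":
    main()
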