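#!/usr/bin/env python
"""Fibre-parameter calibration sweep.

The annulus fibre stiffness (k1, k2) and lamellar angles are not part of
the printed material set; they are calibrated here against the creep
response of the healthy disc under sustained 0.5 MPa compression
(in-vivo height loss 10-15%, instantaneous response a few percent).

Run:  python scripts/calibrate_fibres.py [--resolution 1]

Prints, for each candidate, the equilibrated baseline height, the
instantaneous (5 min) height loss and the 7 h height loss.  The package
defaults (k1=20 MPa, k2=100, angles AFI 35 deg / AFO 25 deg) were chosen
from this sweep; see docs/methods.md for the discussion.
"""

from __future__ import annotations

import argparse
import dataclasses
import sys
import time
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import discflux as dx                                 # noqa: E402
from discflux.poromechanics import LoadProtocol, PoroSolver  # noqa: E402

CANDIDATES = [
    # (k1 MPa, k2, angle AFI deg, angle AFO deg)
    (1.0, 100.0, 45.0, 30.0),
    (20.0, 100.0, 45.0, 30.0),
    (20.0, 100.0, 35.0, 25.0),
    (50.0, 200.0, 35.0, 25.0),
    (100.0, 200.0, 35.0, 25.0),
]


def creep_response(k1, k2, ang_i, ang_o, resolution):
    params = dx.load_parameter_set("healthy")
    params.regions["AFI"] = dataclasses.replace(
        params.regions["AFI"], k1=k1, k2=k2, fibre_angle_deg=ang_i)
    params.regions["AFO"] = dataclasses.replace(
        params.regions["AFO"], k1=k1, k2=k2, fibre_angle_deg=ang_o)
    mesh = dx.build_disc_mesh(dx.DiscGeometrySpec(resolution=resolution))
    solver = PoroSolver(mesh, params)
    baseline = solver.equilibrate(0.1)
    states = solver.run_protocol(LoadProtocol.constant(0.5, 7 * 3600.0),
                                 equilibrate=False)
    h0 = baseline.height
    t = [s.time for s in states]
    import numpy as np
    h5min = states[int(np.argmin(np.abs(np.array(t) - 300.0)))].height
    return h0, 100 * (h0 - h5min) / h0, 100 * (h0 - states[-1].height) / h0


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--resolution", type=int, default=1)
    args = parser.parse_args()
    warnings.filterwarnings("ignore")
    print("k1      k2    angles      h0 [mm]  5min [%]  7h [%]")
    for k1, k2, ai, ao in CANDIDATES:
        t0 = time.time()
        h0, inst, h7 = creep_response(k1, k2, ai, ao, args.resolution)
        print(f"{k1:6.1f} {k2:5.0f}  {ai:.0f}/{ao:.0f} deg   "
              f"{h0:7.2f} {inst:8.1f} {h7:7.1f}   "
              f"[{time.time() - t0:.0f} s]")


if __name__ == "__main__":
    main()
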