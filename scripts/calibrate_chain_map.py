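"""Calibration tool for the default chain-model energy map.

Reproduces how the default dominant-well position and template substituent
tilts were chosen: for candidate (phi, psi) placements it reports the
regular-helix descriptors (radius of the residue-centroid orbit, rise per
residue, residues per turn) from the screw decomposition of the
residue-to-residue rigid transform, and the first interior Kratky maximum
of the DP-50 Debye curve.  The frozen defaults put that maximum near
q = 2 nm^-1, the position observed for amylose in alkaline solution.

Run:  python scripts/calibrate_chain_map.py [--fine]
"""

import argparse

import numpy as np

from amylogel.chain import (
    _ATOM_ORDER,
    debye_intensity,
    delta_energy_map,
    generate_chain,
    glucose_template,
    model_kratky_maximum,
)
from amylogel.errors import PeakNotFoundError


def screw_descriptors(phi0: float, psi0: float, template=None):
    """Helix radius (nm), rise per residue (nm) and residues per turn of the
    regular helix generated by a fixed (phi, psi)."""
    chain = generate_chain(3, delta_energy_map(phi0, psi0), seed=0,
                           template=template)
    n = len(_ATOM_ORDER)
    p0, p1 = chain.positions[:n], chain.positions[n:2 * n]
    c0, c1 = p0.mean(0), p1.mean(0)
    H = (p0 - c0).T @ (p1 - c1)
    U, _, Vt = np.linalg.svd(H)
    det = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, det]) @ U.T
    t = c1 - R @ c0
    ang = np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0))
    if ang < 1e-6:
        return 0.0, float(np.linalg.norm(t)), np.inf
    w, V = np.linalg.eig(R)
    axis = np.real(V[:, np.argmin(np.abs(w - 1.0))])
    axis /= np.linalg.norm(axis)
    rise = abs(float(np.dot(t, axis)))
    t_perp = t - np.dot(t, axis) * axis
    radius = float(np.linalg.norm(t_perp) / (2.0 * np.sin(ang / 2.0)))
    return radius, rise, float(2.0 * np.pi / ang)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fine", action="store_true",
                        help="5-degree scan (slow) instead of 15-degree")
    args = parser.parse_args()
    step = 5 if args.fine else 15

    template = glucose_template()
    print(f"{'phi':>5} {'psi':>5} {'radius':>7} {'rise':>6} {'n/turn':>7} {'q_peak':>7}")
    for phi0 in range(-180, 180, step):
        for psi0 in range(-180, 180, step):
            radius, rise, per_turn = screw_descriptors(phi0, psi0, template)
            if radius < 0.36 or rise < 0.04 or not (4.8 < per_turn < 9):
                continue
            chain = generate_chain(50, delta_energy_map(phi0, psi0), seed=0,
                                   template=template)
            curve = debye_intensity(chain, np.linspace(0.1, 4.0, 200))
            try:
                q_peak = model_kratky_maximum(curve)
            except PeakNotFoundError:
                continue
            print(f"{phi0:5d} {psi0:5d} {radius:7.3f} {rise:6.3f} "
                  f"{per_turn:7.2f} {q_peak:7.3f}")


if __name__ == "__main__":
    main()
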