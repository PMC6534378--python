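"""Extracellular potentials by the line-source approximation.

Each neural segment is treated as a uniform line of transmembrane
current in an infinite Ohmic medium of conductivity sigma; the
potential it generates at an electrode is its current times a transfer
resistance that depends only on geometry and sigma.  The LFP at an
electrode is the sum over segments of transferR x I_segment; point
cells (optionally included) contribute through the point-source term.

Units: positions in µm, sigma in S/m, currents in nA, transfer
resistances in MΩ (so R·I is in mV; LFP is reported in µV).
"""

from __future__ import annotations

import numpy as np

__all__ = ["line_source_phi", "point_source_phi", "ElectrodeArray",
           "compute_lfp"]

def _transfer_unit(sigma):
    # R[Ω] = 1/(4πσ[S/m] d[m]); with d in µm the 1e6 from m->µm and
    # the 1e-6 from Ω->MΩ cancel: R[MΩ] = 1/(4πσ d[µm])
    return 1.0 / (4.0 * np.pi * sigma)


def point_source_phi(source, electrode, sigma=0.3, r_min=1.0):
    """Transfer resistance (MΩ) of a point current source."""
    d = np.linalg.norm(np.asarray(electrode, dtype=float)
                       - np.asarray(source, dtype=float))
    return _transfer_unit(sigma) / max(d, r_min)


def line_source_phi(seg_start, seg_end, electrode, sigma=0.3, r_min=None,
                    diam=1.0):
    """Transfer resistance (MΩ) of a uniform line source.

    The closed form is 1/(4πσΔs) · ln[(√(h²+r²) − h)/(√(l²+r²) − l)]
    with r the radial distance of the electrode to the segment's line
    and h, l the signed longitudinal distances to its two ends.  The
    radial distance is clamped below at the segment radius (``r_min``
    defaults to diam/2) so an electrode on the line never yields an
    infinite potential.
    """
    a = np.asarray(seg_start, dtype=float)
    b = np.asarray(seg_end, dtype=float)
    p = np.asarray(electrode, dtype=float)
    ds = np.linalg.norm(b - a)
    if ds <= 0:
        raise ValueError("segment length must be > 0")
    u = (b - a) / ds
    s = float(np.dot(p - a, u))        # longitudinal position along line
    r = float(np.linalg.norm((p - a) - s * u))
    if r_min is None:
        r_min = diam / 2.0
    r = max(r, r_min)
    # exact integral of 1/distance along the segment
    hi = ds - s                         # distance to far end (signed)
    lo = -s                             # distance to near end (signed)
    num = np.sqrt(r * r + hi * hi) + hi
    den = np.sqrt(r * r + lo * lo) + lo
    return _transfer_unit(sigma) / ds * float(np.log(num / den))


class ElectrodeArray:
    """A set of extracellular electrodes with cached transfer matrices.

    transferR entries are nonnegative-finite by construction (the
    near-field clamp removes the on-line singularity) and depend only
    on geometry and sigma.
    """

    def __init__(self, positions, sigma=0.3, r_min=None):
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        self.sigma = float(sigma)
        self.r_min = r_min

    def transfer_segments(self, p0, p1, diam):
        """(electrodes x segments) transfer resistances, MΩ."""
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        diam = np.asarray(diam, dtype=float)
        out = np.zeros((len(self.positions), len(p0)))
        for e, pos in enumerate(self.positions):
            for s in range(len(p0)):
                r_min = self.r_min if self.r_min is not None \
                    else diam[s] / 2.0
                out[e, s] = line_source_phi(p0[s], p1[s], pos,
                                            sigma=self.sigma,
                                            r_min=r_min, diam=diam[s])
        return out

    def transfer_points(self, positions):
        positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        out = np.zeros((len(self.positions), len(positions)))
        for e, pos in enumerate(self.positions):
            for s, src in enumerate(positions):
                out[e, s] = point_source_phi(
                    src, pos, sigma=self.sigma,
                    r_min=self.r_min if self.r_min is not None else 1.0)
        return out


def compute_lfp(currents, transfer):
    """LFP matrix in µV from per-segment currents (nA) over time.

    ``currents`` is (segments x samples), ``transfer`` (electrodes x
    segments, MΩ); the result is linear in the currents.
    """
    currents = np.asarray(currents, dtype=float)
    transfer = np.asarray(transfer, dtype=float)
    if transfer.shape[1] != currents.shape[0]:
        raise ValueError(
            f"dimension mismatch: transfer has {transfer.shape[1]} "
            f"segments, currents {currents.shape[0]}")
    return 1000.0 * transfer @ currents  # MΩ·nA = mV -> µV
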