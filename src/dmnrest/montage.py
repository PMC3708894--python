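"""International 10-20 electrode geometry and the 12-region DMN parcellation.

Coordinates use a head-centred RAS frame (x toward the right ear, y toward
the nasion, z toward the vertex, metres).  Electrodes sit on the outer
(scalp) sphere of the three-shell head model; the canonical positions are
constructed from the classical 10-20 angular layout: midline and temporal
rows at fixed inclination/azimuth, with F3/F4 and P3/P4 placed halfway
along the great-circle arcs Fz--F7/F8 and Pz--T5/T6.
"""

from __future__ import annotations

import numpy as np

#: Canonical order of the 19 scalp channels.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

#: Mastoid reference channels carried by synthetic recordings.
MASTOIDS: tuple[str, ...] = ("A1", "A2")

#: Canonical order of the 12 default-mode-network regions of interest.
ROI_ORDER: tuple[str, ...] = (
    "MFC_L", "MFC_R", "ACC_L", "ACC_R", "MT_L", "MT_R",
    "IPC_L", "IPC_R", "PCC_L", "PCC_R", "PCu_L", "PCu_R",
)

#: Posterior ROIs used for individual-alpha-frequency detection.
POSTERIOR_ROIS: tuple[str, ...] = (
    "IPC_L", "IPC_R", "PCC_L", "PCC_R", "PCu_L", "PCu_R",
)

# (inclination from vertex, azimuth from anterior midline, +azimuth = right),
# degrees.  The classical "10-20 on a sphere" construction.
_ANGULAR: dict[str, tuple[float, float]] = {
    "Cz": (0.0, 0.0),
    "Fz": (45.0, 0.0),
    "Pz": (45.0, 180.0),
    "C3": (45.0, -90.0),
    "C4": (45.0, 90.0),
    "Fp1": (90.0, -18.0),
    "Fp2": (90.0, 18.0),
    "F7": (90.0, -54.0),
    "F8": (90.0, 54.0),
    "T3": (90.0, -90.0),
    "T4": (90.0, 90.0),
    "T5": (90.0, -126.0),
    "T6": (90.0, 126.0),
    "O1": (90.0, -162.0),
    "O2": (90.0, 162.0),
    "A1": (115.0, -95.0),
    "A2": (115.0, 95.0),
}

# channels defined as great-circle midpoints of two angular anchors
_MIDPOINTS: dict[str, tuple[str, str]] = {
    "F3": ("Fz", "F7"),
    "F4": ("Fz", "F8"),
    "P3": ("Pz", "T5"),
    "P4": ("Pz", "T6"),
}

# Canonical DMN ROI centroids (metres, RAS); mirrored across x = 0.
# Loci: medial frontal, anterior cingulate, medial temporal, inferior
# parietal, posterior cingulate and precuneal positions inside the inner
# (brain) shell of radius 0.087 m.
_ROI_CENTROIDS_RIGHT: dict[str, tuple[float, float, float]] = {
    "MFC": (0.012, 0.055, 0.040),
    "ACC": (0.010, 0.035, 0.030),
    "MT": (0.038, -0.010, -0.020),
    "IPC": (0.045, -0.050, 0.040),
    "PCC": (0.010, -0.048, 0.030),
    "PCu": (0.010, -0.060, 0.048),
}


def _unit_from_angles(theta_deg: float, az_deg: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    az = np.deg2rad(az_deg)
    return np.array([np.sin(th) * np.sin(az), np.sin(th) * np.cos(az), np.cos(th)])


def _slerp_mid(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    w = u + v
    return w / np.linalg.norm(w)


def electrode_unit_vectors(labels: tuple[str, ...] = CHANNELS_1020) -> np.ndarray:
    """Unit direction vectors of the requested electrodes, shape (n, 3)."""
    out = []
    for lab in labels:
        if lab in _ANGULAR:
            out.append(_unit_from_angles(*_ANGULAR[lab]))
        elif lab in _MIDPOINTS:
            a, b = _MIDPOINTS[lab]
            out.append(_slerp_mid(_unit_from_angles(*_ANGULAR[a]),
                                  _unit_from_angles(*_ANGULAR[b])))
        else:
            raise KeyError(f"unknown electrode label: {lab}")
    return np.asarray(out)


def electrode_positions(scalp_radius: float = 0.1,
                        labels: tuple[str, ...] = CHANNELS_1020) -> np.ndarray:
    """Electrode positions on the scalp sphere, shape (n, 3), metres."""
    return scalp_radius * electrode_unit_vectors(labels)


def roi_centroid(roi: str) -> np.ndarray:
    """Canonical centroid of one of the 12 DMN ROIs (metres)."""
    base, hemi = roi.rsplit("_", 1)
    x, y, z = _ROI_CENTROIDS_RIGHT[base]
    if hemi == "L":
        x = -x
    elif hemi != "R":
        raise KeyError(f"unknown ROI: {roi}")
    return np.array([x, y, z])


def roi_pairs(rois: tuple[str, ...] = ROI_ORDER) -> list[tuple[str, str]]:
    """All unordered ROI pairs in canonical (lexicographic-over-order) order.

    12 ROIs yield the 66 pairs that, crossed with the 7 frequency bands,
    form the 462-test battery submitted to FDR correction.
    """
    return [(rois[i], rois[j]) for i in range(len(rois)) for j in range(i + 1, len(rois))]


def pair_label(a: str, b: str) -> str:
    return f"{a}--{b}"
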