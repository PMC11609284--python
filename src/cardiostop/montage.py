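"""Idealized 64-channel 10-10 electrode montage.

Electrode positions are constructed on a sphere of radius 9 cm (a typical
adult head) from the standard 10-10 layout: the midline chain and the outer
10% ring are placed at fixed polar angles, and intermediate electrodes are
great-circle interpolated between their midline and outer-ring anchors.
Coordinates are head-centered centimetres: +x right, +y anterior, +z up.

The montage is also shipped as a packaged TSV (``data/montage64.tsv``) so
downstream stages and external tools can read it as a plain file.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

HEAD_RADIUS_CM = 9.0

# Outer (10%) ring: polar angle 72 deg from vertex, azimuth in 18 deg steps.
# Azimuth convention: 0 deg = right preauricular (+x), 90 deg = nasion (+y).
_RING_AZ = {
    "Fp1": 108.0, "Fp2": 72.0,
    "AF7": 126.0, "AF8": 54.0,
    "F7": 144.0, "F8": 36.0,
    "FT7": 162.0, "FT8": 18.0,
    "T7": 180.0, "T8": 0.0,
    "TP7": 198.0, "TP8": 342.0,
    "P7": 216.0, "P8": 324.0,
    "PO7": 234.0, "PO8": 306.0,
    "O1": 252.0, "O2": 288.0,
    "Oz": 270.0,
}

# Midline chain: (polar angle from vertex, azimuth).
_MIDLINE = {
    "AFz": (54.0, 90.0),
    "Fz": (36.0, 90.0),
    "FCz": (18.0, 90.0),
    "Cz": (0.0, 90.0),
    "CPz": (18.0, 270.0),
    "Pz": (36.0, 270.0),
    "POz": (54.0, 270.0),
    "Oz": (72.0, 270.0),
}

# Interpolated rows: midline anchor, outer anchor (left), and the fractional
# positions of the intermediate electrodes along the great circle.
_ROWS = [
    ("Fz", "F7", {"F1": 0.25, "F3": 0.50, "F5": 0.75}),
    ("FCz", "FT7", {"FC1": 0.25, "FC3": 0.50, "FC5": 0.75}),
    ("Cz", "T7", {"C1": 0.25, "C3": 0.50, "C5": 0.75}),
    ("CPz", "TP7", {"CP1": 0.25, "CP3": 0.50, "CP5": 0.75}),
    ("Pz", "P7", {"P1": 0.25, "P3": 0.50, "P5": 0.75}),
    ("AFz", "AF7", {"AF3": 0.50}),
    ("POz", "PO7", {"PO3": 0.50}),
]

# Inferior temporal sites: 10% below the ring along the same azimuth.
_INFERIOR = {"FT9": 162.0, "TP9": 198.0, "FT10": 18.0, "TP10": 342.0}

CHANNELS_64 = [
    "Fp1", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
]


def _sph(polar_deg: float, az_deg: float) -> np.ndarray:
    th = np.deg2rad(polar_deg)
    az = np.deg2rad(az_deg)
    return np.array([np.sin(th) * np.cos(az), np.sin(th) * np.sin(az), np.cos(th)])


def _slerp(a: np.ndarray, b: np.ndarray, f: float) -> np.ndarray:
    omega = np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))
    if omega < 1e-12:
        return a
    return (np.sin((1 - f) * omega) * a + np.sin(f * omega) * b) / np.sin(omega)


def _mirror(label: str) -> str:
    """Left-hemisphere label -> right-hemisphere label (odd -> even index)."""
    for n in ("9", "7", "5", "3", "1"):
        if label.endswith(n):
            return label[: -len(n)] + str(int(n) + 1)
    return label


def ideal_1010_positions(radius_cm: float = HEAD_RADIUS_CM) -> pd.DataFrame:
    """Compute the idealized 64-channel montage.

    Returns a DataFrame with columns ``label, x_cm, y_cm, z_cm`` in the
    canonical channel order.
    """
    unit: dict[str, np.ndarray] = {}
    for lab, az in _RING_AZ.items():
        unit[lab] = _sph(72.0, az)
    for lab, (pol, az) in _MIDLINE.items():
        unit[lab] = _sph(pol, az)
    for mid, outer, fracs in _ROWS:
        for lab, f in fracs.items():
            v = _slerp(unit[mid], unit[outer], f)
            unit[lab] = v / np.linalg.norm(v)
            right = _mirror(lab)
            vr = v * np.array([-1.0, 1.0, 1.0])
            unit[right] = vr / np.linalg.norm(vr)
    for lab, az in _INFERIOR.items():
        unit[lab] = _sph(90.0, az)

    rows = []
    for lab in CHANNELS_64:
        v = unit[lab] * radius_cm
        rows.append((lab, v[0], v[1], v[2]))
    return pd.DataFrame(rows, columns=["label", "x_cm", "y_cm", "z_cm"])


def load_montage(montage_id: str = "standard64") -> pd.DataFrame:
    """Load the packaged montage TSV (labels + head-centered cm coordinates)."""
    if montage_id != "standard64":
        raise ValueError(f"unknown montage_id: {montage_id!r}")
    with resources.files("cardiostop").joinpath("data/montage64.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def subset_montage(montage: pd.DataFrame, labels: list[str]) -> pd.DataFrame:
    """Restrict a montage to a channel subset, preserving the given order."""
    missing = [c for c in labels if c not in set(montage["label"])]
    if missing:
        raise KeyError(f"channels not in montage: {missing}")
    out = montage.set_index("label").loc[labels].reset_index()
    return out


def channel_angles(montage: pd.DataFrame) -> np.ndarray:
    """Pairwise great-circle angles (deg) between electrodes."""
    xyz = montage[["x_cm", "y_cm", "z_cm"]].to_numpy()
    u = xyz / np.linalg.norm(xyz, axis=1, keepdims=True)
    cos = np.clip(u @ u.T, -1.0, 1.0)
    return np.rad2deg(np.arccos(cos))


def gaussian_scalp_pattern(
    montage: pd.DataFrame, center_labels: list[str] | str, sigma_deg: float = 22.0
) -> np.ndarray:
    """Smooth spatial weight map: Gaussian in great-circle angle around the
    centroid of ``center_labels``, normalized to peak 1."""
    if isinstance(center_labels, str):
        center_labels = [center_labels]
    xyz = montage.set_index("label")[["x_cm", "y_cm", "z_cm"]]
    c = xyz.loc[center_labels].to_numpy().mean(axis=0)
    c = c / np.linalg.norm(c)
    u = montage[["x_cm", "y_cm", "z_cm"]].to_numpy()
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    ang = np.rad2deg(np.arccos(np.clip(u @ c, -1.0, 1.0)))
    w = np.exp(-0.5 * (ang / sigma_deg) ** 2)
    return w / w.max()
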