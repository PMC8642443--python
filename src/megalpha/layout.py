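"""Synthetic MEG sensor layout: 102 colocated triplets on a spherical cap.

Each triplet holds one magnetometer (radially oriented) and two orthogonal
planar gradiometers (tangentially oriented), mimicking a 306-channel
whole-head system.  Placement is a deterministic Fibonacci spiral on a
spherical cap above the head-model origin, so layouts are reproducible
without any digitizer file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

#: anatomical-style octant labels: left/right x frontal, temporal, parietal, occipital
REGION_LABELS = ("LF", "RF", "LT", "RT", "LP", "RP", "LO", "RO")

HEAD_RADIUS = 0.09  # m, spherical head-model radius
SENSOR_RADIUS = 0.102  # m, magnetometer shell radius


@dataclass(frozen=True)
class SensorLayout:
    """Positions and orientations of colocated magnetometer/gradiometer triplets.

    Attributes
    ----------
    positions : (n, 3) float array
        Triplet positions in metres, on a spherical cap centred above the origin.
    mag_orientations : (n, 3) float array
        Radial unit vectors (magnetometer coil normals).
    grad_orientations : (n, 2, 3) float array
        Two orthogonal tangential unit vectors per triplet (planar-gradiometer
        sensitive directions).
    region_labels : (n,) array of str
        One of ``REGION_LABELS`` per triplet.
    """

    positions: np.ndarray
    mag_orientations: np.ndarray
    grad_orientations: np.ndarray
    region_labels: np.ndarray
    sensor_radius: float = SENSOR_RADIUS
    head_radius: float = HEAD_RADIUS

    def __post_init__(self) -> None:
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n, 3)")
        if self.mag_orientations.shape != (n, 3):
            raise ValueError("mag_orientations must be (n, 3)")
        if self.grad_orientations.shape != (n, 2, 3):
            raise ValueError("grad_orientations must be (n, 2, 3)")

    @property
    def n_triplets(self) -> int:
        return self.positions.shape[0]

    @property
    def n_channels(self) -> int:
        """Total physical channels: 1 magnetometer + 2 gradiometers per triplet."""
        return 3 * self.n_triplets

    def channel_names(self) -> list[str]:
        """MAG/GRAD channel names in triplet-major order (mag, grad1, grad2)."""
        names = []
        for i in range(self.n_triplets):
            names += [f"MEG{i:03d}1", f"MEG{i:03d}2", f"MEG{i:03d}3"]
        return names

    def is_posterior(self) -> np.ndarray:
        """Boolean mask of triplets in parietal/occipital octants."""
        return np.isin(self.region_labels, ("LP", "RP", "LO", "RO"))


def _region_of(position: np.ndarray) -> str:
    """Octant label from sensor position.

    The head coordinate frame is x = left(-) / right(+), y = posterior(-) /
    anterior(+), z = up.  Anterior-posterior position is cut into four bands
    (frontal, temporal, parietal, occipital) by the polar angle of y.
    """
    x, y, _ = position
    lr = "L" if x < 0 else "R"
    # normalised anterior-posterior coordinate in [-1, 1]
    ya = y / np.linalg.norm(position)
    if ya > 0.33:
        band = "F"
    elif ya > 0.0:
        band = "T"
    elif ya > -0.45:
        band = "P"
    else:
        band = "O"
    return lr + band


def make_layout(n_triplets: int = 102, cap_half_angle: float = 110.0) -> SensorLayout:
    """Build a deterministic quasi-uniform sensor triplet layout.

    Parameters
    ----------
    n_triplets : int
        Number of triplet sites (default 102, i.e. 102 magnetometers and
        204 planar gradiometers).
    cap_half_angle : float
        Half-opening angle of the spherical cap in degrees, measured from the
        +z axis.  110 degrees covers the head down to below the ears.

    Returns
    -------
    SensorLayout

    Notes
    -----
    Sites follow a Fibonacci spiral restricted to the cap, which is
    deterministic and quasi-uniform.  Tangential gradiometer axes are the
    local spherical unit vectors (e_theta, e_phi), hence orthogonal to each
    other and to the radial magnetometer normal.
    """
    if n_triplets < 4:
        raise ValueError(f"n_triplets must be >= 4, got {n_triplets}")
    if not 0 < cap_half_angle <= 180:
        raise ValueError("cap_half_angle must be in (0, 180] degrees")

    golden = (1.0 + np.sqrt(5.0)) / 2.0
    i = np.arange(n_triplets)
    # uniform in cos(theta) over the cap -> equal-area rings
    cos_max = np.cos(np.deg2rad(cap_half_angle))
    z = 1.0 - (1.0 - cos_max) * (i + 0.5) / n_triplets
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = 2.0 * np.pi * i / golden

    radial = np.column_stack(
        [
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
            np.cos(theta),
        ]
    )
    positions = SENSOR_RADIUS * radial

    # local tangential frame: e_theta (towards increasing polar angle), e_phi
    e_theta = np.column_stack(
        [
            np.cos(theta) * np.cos(phi),
            np.cos(theta) * np.sin(phi),
            -np.sin(theta),
        ]
    )
    e_phi = np.column_stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)])
    grad = np.stack([e_theta, e_phi], axis=1)

    labels = np.array([_region_of(p) for p in positions])
    return SensorLayout(
        positions=positions,
        mag_orientations=radial,
        grad_orientations=grad,
        region_labels=labels,
    )


def build_adjacency(
    layout: SensorLayout,
    method: str = "delaunay",
    radius: float | None = None,
) -> np.ndarray:
    """Sensor-triplet neighbouring matrix for spatial clustering.

    Parameters
    ----------
    layout : SensorLayout
    method : {"delaunay", "distance"}
        ``delaunay``: neighbours are edges of the Delaunay triangulation of
        the sensors' azimuthal-equidistant plane projection (the standard way
        a neighbouring matrix is derived from a cap of sensors).
        ``distance``: neighbours are pairs closer than ``radius`` metres.
    radius : float, optional
        Required for the distance method.

    Returns
    -------
    (n, n) bool array
        Symmetric with a zero diagonal.
    """
    n = layout.n_triplets
    adj = np.zeros((n, n), dtype=bool)
    if method == "delaunay":
        pts2d = azimuthal_projection(layout.positions)
        tri = Delaunay(pts2d)
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    adj[simplex[a], simplex[b]] = True
                    adj[simplex[b], simplex[a]] = True
    elif method == "distance":
        if radius is None or radius <= 0:
            raise ValueError("distance method requires radius > 0")
        d = np.linalg.norm(layout.positions[:, None] - layout.positions[None], axis=-1)
        adj = (d > 0) & (d <= radius)
    else:
        raise ValueError(f"unknown adjacency method: {method!r}")

    np.fill_diagonal(adj, False)
    if method == "distance" and (adj.sum(axis=1) == 0).any():
        warnings.warn(
            "adjacency: some triplets have no neighbour at this radius; "
            "the layout is disconnected",
            stacklevel=2,
        )
    return adj


def azimuthal_projection(positions: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection of sensor positions onto 2-D.

    Maps each position to polar coordinates (theta, phi) about +z and plots
    at radius theta — the flattened 'topographic map' plane used both for
    Delaunay adjacency and for topography exports.
    """
    r = np.linalg.norm(positions, axis=1)
    theta = np.arccos(np.clip(positions[:, 2] / r, -1, 1))
    phi = np.arctan2(positions[:, 1], positions[:, 0])
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])
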