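"""Simplified source-space stage on a spherical conductor.

An octahedral cortical grid (recursively quadrisected octahedron projected
to a sphere), the analytic magnetic field of a current dipole in a
spherically symmetric conductor (Sarvas' closed form) as the forward model,
noise-covariance whitening, an L2 minimum-norm inverse, and per-vertex
source band power in dB.

The spherically symmetric conductor has the classic silent-source property:
a radially oriented dipole produces no external magnetic field.  A perfect
sphere's outward normals are radial, so "normally oriented" sources on an
undeformed spherical shell would all be silent; :func:`folded_normals`
therefore tilts the normals according to a smooth synthetic folding
pattern, emulating the non-radial orientations of a convoluted cortex while
keeping the vertex grid spherical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .layout import SensorLayout
from .spectral import PSDResult, band_power, welch_psd

MU0_OVER_4PI = 1e-7  # T·m/A

DB_FLOOR = -300.0  # dB floor reported for zero source power

GRAD_BASELINE = 0.0168  # m, planar-gradiometer finite-difference baseline


@dataclass(frozen=True)
class SourceSpace:
    """Triangulated spherical cortical grid with per-vertex dipole normals."""

    vertices: np.ndarray  # (n, 3), on a sphere of the given radius
    normals: np.ndarray  # (n, 3), unit
    faces: np.ndarray  # (m, 3) int
    radius: float
    subdivision_depth: int

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_edges(self) -> int:
        edges = set()
        for tri in self.faces:
            for a in range(3):
                e = (int(tri[a]), int(tri[(a + 1) % 3]))
                edges.add((min(e), max(e)))
        return len(edges)

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.faces.shape[0]

    def adjacency(self) -> np.ndarray:
        """Vertex adjacency (mesh edges) for source-space clustering."""
        n = self.n_vertices
        adj = np.zeros((n, n), dtype=bool)
        for tri in self.faces:
            for a in range(3):
                i, j = int(tri[a]), int(tri[(a + 1) % 3])
                adj[i, j] = adj[j, i] = True
        np.fill_diagonal(adj, False)
        return adj


@dataclass(frozen=True)
class ForwardOperator:
    """Sensor lead field of fixed-orientation dipoles.

    Rows are physical channels in triplet-major order (magnetometer in
    T per A·m, then the two planar gradiometers in T/m per A·m); columns
    are sources.
    """

    lead_field: np.ndarray  # (n_channels, n_sources)
    sphere_center: np.ndarray
    conductor_radius: float


@dataclass(frozen=True)
class InverseOperator:
    """Minimum-norm inverse: kernel applied to whitened sensor data."""

    kernel: np.ndarray  # (n_sources, n_channels), maps *whitened* data
    whitener: np.ndarray  # (n_channels, n_channels)
    lambda2: float

    def apply(self, data: np.ndarray) -> np.ndarray:
        """Source time courses from raw (unwhitened) sensor data."""
        return self.kernel @ (self.whitener @ data)


def octahedral_source_space(depth: int, radius: float = 0.07) -> SourceSpace:
    """Recursively quadrisected octahedron projected onto a sphere.

    Each subdivision step splits every triangle into four via edge midpoints
    projected to the sphere, giving ``2 + 4**(depth + 1)`` unique vertices
    (depth 5: 4098 — the conventional per-hemisphere dipole count).
    Normals default to the outward radial direction.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth > 7:
        raise ValueError("depth > 7 refused (memory guard)")
    verts = np.array(
        [
            [1.0, 0, 0],
            [-1.0, 0, 0],
            [0, 1.0, 0],
            [0, -1.0, 0],
            [0, 0, 1.0],
            [0, 0, -1.0],
        ]
    )
    faces = np.array(
        [
            [0, 2, 4],
            [2, 1, 4],
            [1, 3, 4],
            [3, 0, 4],
            [2, 0, 5],
            [1, 2, 5],
            [3, 1, 5],
            [0, 3, 5],
        ]
    )
    vlist = [v for v in verts]
    for _ in range(depth):
        midpoint_cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in midpoint_cache:
                m = vlist[i] + vlist[j]
                m = m / np.linalg.norm(m)
                midpoint_cache[key] = len(vlist)
                vlist.append(m)
            return midpoint_cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        faces = np.array(new_faces)
    vertices = np.array(vlist)
    return SourceSpace(
        vertices=radius * vertices,
        normals=vertices.copy(),
        faces=faces,
        radius=radius,
        subdivision_depth=depth,
    )


def folded_normals(
    space: SourceSpace, tilt: float = 1.0, angular_frequency: int = 6
) -> SourceSpace:
    """Tilt dipole normals by a smooth synthetic folding pattern.

    The normal at each vertex is the radial direction plus ``tilt`` times a
    tangential field derived from a sinusoidal "folding" pattern in the
    spherical angles, renormalised to unit length.  ``tilt = 0`` returns
    radial (silent) normals; ``tilt = 1`` tilts normals by about 45 deg.
    """
    r = space.vertices / np.linalg.norm(space.vertices, axis=1, keepdims=True)
    theta = np.arccos(np.clip(r[:, 2], -1, 1))
    phi = np.arctan2(r[:, 1], r[:, 0])
    e_theta = np.column_stack(
        [np.cos(theta) * np.cos(phi), np.cos(theta) * np.sin(phi), -np.sin(theta)]
    )
    e_phi = np.column_stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)])
    w = angular_frequency
    tang = (
        np.cos(w * phi)[:, None] * e_theta + np.sin(w * theta)[:, None] * e_phi
    )
    normals = r + tilt * tang
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return replace(space, normals=normals)


def sarvas_field(
    dipole_pos: np.ndarray, dipole_moment: np.ndarray, sensor_pos: np.ndarray
) -> np.ndarray:
    """Magnetic field of a current dipole in a spherically symmetric conductor.

    Closed-form solution with the conductor centred at the origin.  Volume
    currents are fully accounted for; the result is independent of the
    conductivity profile.  Inputs in SI (m, A·m); output in tesla.
    """
    r0 = np.asarray(dipole_pos, dtype=float)
    q = np.asarray(dipole_moment, dtype=float)
    r = np.atleast_2d(np.asarray(sensor_pos, dtype=float))
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a == 0):
        raise ValueError("sensor coincides with the dipole")
    adotr = np.einsum("ij,ij->i", a_vec, r)
    f = a * (rn * a + rn**2 - r0 @ r.T)
    grad_f = (
        (a**2 / rn + adotr / a + 2 * a + 2 * rn)[:, None] * r
        - (a + 2 * rn + adotr / a)[:, None] * r0[None, :]
    )
    qxr0 = np.cross(q, r0)
    b = MU0_OVER_4PI / f[:, None] ** 2 * (
        f[:, None] * qxr0[None, :] - (r @ qxr0)[:, None] * grad_f
    )
    if sensor_pos.ndim == 1:
        return b[0]
    return b


def sarvas_forward(
    sources: SourceSpace,
    layout: SensorLayout,
    sphere_center: np.ndarray | None = None,
    grad_baseline: float = GRAD_BASELINE,
) -> ForwardOperator:
    """Lead field of the source grid's fixed-orientation dipoles.

    Magnetometer rows project the analytic field onto the radial coil
    normal; planar-gradiometer rows are tangential finite differences of
    that projection over ``grad_baseline``.  All sources must lie strictly
    inside, and all sensors strictly outside, the conductor sphere.
    """
    center = np.zeros(3) if sphere_center is None else np.asarray(sphere_center)
    spos = layout.positions - center
    vpos = sources.vertices - (0 if sphere_center is None else center)
    conductor_radius = layout.head_radius
    sensor_r = np.linalg.norm(spos, axis=1)
    if np.any(sensor_r <= conductor_radius):
        raise ValueError("all sensors must lie strictly outside the conductor")
    if np.any(np.linalg.norm(vpos, axis=1) >= conductor_radius):
        raise ValueError("all sources must lie strictly inside the conductor")

    n_src = sources.n_vertices
    n_trip = layout.n_triplets
    lead = np.zeros((3 * n_trip, n_src))
    half = grad_baseline / 2.0
    for j in range(n_src):
        q = sources.normals[j]
        b = sarvas_field(vpos[j], q, spos)
        b_radial = np.einsum("ij,ij->i", b, layout.mag_orientations)
        lead[0::3, j] = b_radial
        for g in range(2):
            u = layout.grad_orientations[:, g, :]
            b_plus = sarvas_field(vpos[j], q, spos + half * u)
            b_minus = sarvas_field(vpos[j], q, spos - half * u)
            d_plus = np.einsum("ij,ij->i", b_plus, layout.mag_orientations)
            d_minus = np.einsum("ij,ij->i", b_minus, layout.mag_orientations)
            lead[1 + g :: 3, j] = (d_plus - d_minus) / grad_baseline
    return ForwardOperator(
        lead_field=lead,
        sphere_center=center,
        conductor_radius=conductor_radius,
    )


def compute_whitener(noise_segments: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Inverse matrix square root of the (diagonally loaded) noise covariance.

    ``noise_segments``: (n_channels, n_samples) baseline sensor data.  The
    covariance is loaded by ``ridge * mean(diagonal) * I`` before inversion;
    whitened noise has covariance approximately the identity, putting
    magnetometers and gradiometers on the same scale.
    """
    x = np.asarray(noise_segments, dtype=float)
    n_ch, n_samp = x.shape
    if n_samp < 2 * n_ch:
        raise ValueError("need at least 2x more samples than channels")
    cov = np.cov(x)
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if ridge > 0:
        cov = cov + ridge * np.mean(np.diag(cov)) * np.eye(n_ch)
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() <= evals.max() * 1e-12:
        raise ValueError(
            "noise covariance is rank deficient; pass a positive ridge "
            "(diagonal loading) to regularise it"
        )
    return (evecs * (1.0 / np.sqrt(evals))) @ evecs.T


def minimum_norm_inverse(
    fwd: ForwardOperator,
    whitener: np.ndarray,
    lambda2: float = 1.0 / 9.0,
    scale_source_cov: bool = True,
) -> InverseOperator:
    """L2 minimum-norm inverse operator.

    kernel = R Lw' (Lw R Lw' + lambda2 I)^-1 for the whitened lead field
    Lw = W L and identity source covariance R.  With ``scale_source_cov``
    (default) R is scaled so that trace(Lw R Lw') equals the number of
    channels, which makes ``lambda2 = 1/9`` the conventional
    signal-to-noise-ratio-3 regularisation.
    """
    if lambda2 <= 0:
        raise ValueError("lambda2 must be positive")
    if not np.all(np.isfinite(fwd.lead_field)):
        raise ValueError("lead field contains non-finite entries")
    lw = whitener @ fwd.lead_field
    n_ch = lw.shape[0]
    r_scale = 1.0
    if scale_source_cov:
        tr = np.trace(lw @ lw.T)
        if tr > 0:
            r_scale = n_ch / tr
    gram = r_scale * (lw @ lw.T) + lambda2 * np.eye(n_ch)
    kernel = r_scale * lw.T @ np.linalg.solve(gram, np.eye(n_ch))
    return InverseOperator(kernel=kernel, whitener=np.asarray(whitener),
                           lambda2=lambda2)


def source_band_power(
    inv: InverseOperator,
    data: np.ndarray,
    band: tuple[float, float],
    sampling_rate: float,
    window_length: int = 512,
) -> np.ndarray:
    """Per-vertex band power of the source estimates, in dB.

    Applies the inverse to the sensor data, computes each source time
    course's Welch PSD (``window_length``-sample Hamming windows, no
    overlap), extracts band power by the closed-bin-centre rule, and
    reports ``10 * log10`` with zero power floored at ``DB_FLOOR`` dB.
    """
    stc = inv.apply(np.asarray(data, dtype=float))
    psd = welch_psd(stc, sampling_rate, window_length=window_length)
    bp = band_power(psd, band)
    out = np.full(bp.shape, DB_FLOOR)
    pos = bp > 0
    out[pos] = 10.0 * np.log10(bp[pos])
    return np.maximum(out, DB_FLOOR)
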