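"""Eye-region area of interest: construction and point-in-polygon tests.

The AOI is one closed simple polygon built from facial landmarks: the
two upper-cheek points form the lower edge beneath the eyes, the
outermost eyebrow landmarks anchor the sides, and a discretized
half-ellipse spanning the outer eyebrow points closes the region over
the forehead.  Gaze samples are classified against the polygon with a
vectorized ray-casting (even-odd crossing) test; points exactly on the
boundary count as inside.

Coordinates follow the image convention: origin at the top-left corner,
x rightward, y downward, units of stimulus pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from .core import GeometryError, SchemaError


@dataclass
class Landmarks:
    """Named facial landmarks in stimulus pixel coordinates."""

    image_id: str
    width: int
    height: int
    eyebrow_left: np.ndarray  # (k, 2) ordered chain
    eyebrow_right: np.ndarray
    cheek_left: np.ndarray  # (2,)
    cheek_right: np.ndarray
    eye_left: np.ndarray
    eye_right: np.ndarray

    def __post_init__(self) -> None:
        for name in ("eyebrow_left", "eyebrow_right"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
                raise SchemaError(f"{name} must be a non-empty (k, 2) chain")
            setattr(self, name, arr)
        for name in ("cheek_left", "cheek_right", "eye_left", "eye_right"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(2)
            setattr(self, name, arr)
        pts = self.all_points()
        if (
            (pts[:, 0] < 0).any()
            or (pts[:, 1] < 0).any()
            or (pts[:, 0] > self.width).any()
            or (pts[:, 1] > self.height).any()
        ):
            raise SchemaError("landmarks fall outside the image frame")
        if np.allclose(self.eye_left, self.eye_right):
            raise SchemaError("left and right eye centers coincide")

    def all_points(self) -> np.ndarray:
        return np.vstack(
            [
                self.eyebrow_left,
                self.eyebrow_right,
                self.cheek_left,
                self.cheek_right,
                self.eye_left,
                self.eye_right,
            ]
        )

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "width": self.width,
            "height": self.height,
            "eyebrow_left": self.eyebrow_left.tolist(),
            "eyebrow_right": self.eyebrow_right.tolist(),
            "cheek_left": self.cheek_left.tolist(),
            "cheek_right": self.cheek_right.tolist(),
            "eye_left": self.eye_left.tolist(),
            "eye_right": self.eye_right.tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Landmarks":
        return cls(
            image_id=data["image_id"],
            width=int(data["width"]),
            height=int(data["height"]),
            eyebrow_left=np.asarray(data["eyebrow_left"], dtype=float),
            eyebrow_right=np.asarray(data["eyebrow_right"], dtype=float),
            cheek_left=np.asarray(data["cheek_left"], dtype=float),
            cheek_right=np.asarray(data["cheek_right"], dtype=float),
            eye_left=np.asarray(data["eye_left"], dtype=float),
            eye_right=np.asarray(data["eye_right"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Landmarks":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class EyeAOI:
    """Closed simple polygon covering both eyes, eyebrows and forehead."""

    vertices: np.ndarray  # (m, 2); implicitly closed (last connects to first)
    image_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise GeometryError("polygon vertices must be (m, 2)")
        if len(self.vertices) < 3:
            raise GeometryError("polygon needs at least 3 vertices")
        if abs(self.area()) < 1e-12:
            raise GeometryError("degenerate polygon with zero area")

    def area(self) -> float:
        """Unsigned polygon area via the shoelace formula."""
        x = self.vertices[:, 0]
        y = self.vertices[:, 1]
        return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def translated(self, dx: float, dy: float) -> "EyeAOI":
        return EyeAOI(self.vertices + np.array([dx, dy]), self.image_id)

    def bounds(self) -> tuple[float, float, float, float]:
        v = self.vertices
        return v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max()


def _outermost(chain: np.ndarray, direction: float) -> np.ndarray:
    """Endpoint of an eyebrow chain that is most lateral along x."""
    idx = np.argmin(chain[:, 0]) if direction < 0 else np.argmax(chain[:, 0])
    return chain[idx]


def build_eye_aoi(
    landmarks: Landmarks,
    ellipse_height_ratio: float = 0.5,
    ellipse_vertices: int = 32,
) -> EyeAOI:
    """Construct the eye-region AOI polygon from facial landmarks.

    The polygon runs ``cheek_left -> cheek_right -> outer right eyebrow
    -> half-ellipse arc over the forehead -> outer left eyebrow`` and
    closes back to the left cheek.  The arc's major axis spans the two
    outermost eyebrow landmarks and its semi-minor axis equals
    ``ellipse_height_ratio`` times the major-axis length; with ratio 0
    the upper boundary degenerates to the straight eyebrow segment.

    Raises
    ------
    GeometryError
        If the landmarks are collinear/degenerate (zero-area polygon).
    """
    if ellipse_height_ratio < 0:
        raise GeometryError("ellipse_height_ratio must be >= 0")
    left_outer = _outermost(landmarks.eyebrow_left, -1)
    right_outer = _outermost(landmarks.eyebrow_right, +1)
    axis = right_outer - left_outer
    major_len = float(np.hypot(*axis))
    if major_len < 1e-9:
        raise GeometryError("outer eyebrow landmarks coincide")
    center = 0.5 * (left_outer + right_outer)
    u = axis / major_len  # unit vector along the major axis
    normal = np.array([-u[1], u[0]])
    # orient the arc away from the cheeks (upward on the face)
    cheek_mid = 0.5 * (landmarks.cheek_left + landmarks.cheek_right)
    if np.dot(normal, cheek_mid - center) > 0:
        normal = -normal
    a = 0.5 * major_len
    b = ellipse_height_ratio * major_len

    verts = [landmarks.cheek_left, landmarks.cheek_right, right_outer]
    if b > 0:
        # arc from the right outer point (theta=0) to the left (theta=pi),
        # interior points only; endpoints are the eyebrow landmarks
        theta = np.linspace(0.0, np.pi, ellipse_vertices + 2)[1:-1]
        arc = center[None, :] + np.outer(a * np.cos(theta), u) + np.outer(
            b * np.sin(theta), normal
        )
        verts.extend(arc)
    verts.append(left_outer)
    aoi = EyeAOI(np.asarray(verts), image_id=landmarks.image_id)
    return aoi


try:  # compiled kernel; the pure-NumPy path below is the reference
    import numba

    @numba.njit(cache=False, fastmath=False)
    def _ray_cast_kernel(x, y, vx, vy, eps):  # pragma: no cover - jitted
        n = x.shape[0]
        m = vx.shape[0]
        out = np.zeros(n, dtype=np.bool_)
        eps2 = eps * eps
        for i in range(n):
            xi = x[i]
            yi = y[i]
            if not (np.isfinite(xi) and np.isfinite(yi)):
                continue
            inside = False
            on_edge = False
            for j in range(m):
                x1 = vx[j]
                y1 = vy[j]
                k = j + 1 if j + 1 < m else 0
                x2 = vx[k]
                y2 = vy[k]
                if (y1 > yi) != (y2 > yi):
                    x_at = x1 + (yi - y1) * (x2 - x1) / (y2 - y1)
                    if xi < x_at:
                        inside = not inside
                ex = x2 - x1
                ey = y2 - y1
                L2 = ex * ex + ey * ey
                if L2 == 0.0:
                    L2 = 1.0
                t = ((xi - x1) * ex + (yi - y1) * ey) / L2
                if t < 0.0:
                    t = 0.0
                elif t > 1.0:
                    t = 1.0
                dx = xi - (x1 + t * ex)
                dy = yi - (y1 + t * ey)
                if dx * dx + dy * dy <= eps2:
                    on_edge = True
            out[i] = inside or on_edge
        return out

except ImportError:  # pragma: no cover
    _ray_cast_kernel = None


def points_in_polygon(points: np.ndarray, polygon: EyeAOI, eps: float = 1e-9) -> np.ndarray:
    """Even-odd ray-casting point-in-polygon test.

    A horizontal ray is cast in +x from each point and edge crossings
    are counted with the half-open rule (each edge includes exactly one
    of its endpoints), so rays through vertices are not double-counted.
    Points within ``eps`` of an edge are classified inside regardless
    of parity.  NaN coordinates return ``False``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if _ray_cast_kernel is not None:
        return _ray_cast_kernel(
            np.ascontiguousarray(pts[:, 0]),
            np.ascontiguousarray(pts[:, 1]),
            np.ascontiguousarray(polygon.vertices[:, 0]),
            np.ascontiguousarray(polygon.vertices[:, 1]),
            float(eps),
        )
    x, y = pts[:, 0], pts[:, 1]
    v = polygon.vertices
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)

    # crossing test: edge straddles the scanline under the half-open rule
    yi = y[:, None]
    xi = x[:, None]
    straddle = (y1[None, :] > yi) != (y2[None, :] > yi)
    with np.errstate(invalid="ignore", divide="ignore"):
        x_at_y = x1[None, :] + (yi - y1[None, :]) * (x2 - x1)[None, :] / (y2 - y1)[None, :]
        crossings = straddle & (xi < x_at_y)
    inside = np.nansum(crossings, axis=1) % 2 == 1

    # boundary inclusion: squared distance from each point to each edge
    ex, ey = (x2 - x1), (y2 - y1)
    seg_len2 = ex**2 + ey**2
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    t = ((xi - x1[None, :]) * ex[None, :] + (yi - y1[None, :]) * ey[None, :]) / seg_len2[None, :]
    t = np.clip(t, 0.0, 1.0)
    dx = xi - (x1[None, :] + t * ex[None, :])
    dy = yi - (y1[None, :] + t * ey[None, :])
    with np.errstate(invalid="ignore"):
        on_edge = np.nanmin(dx**2 + dy**2, axis=1) <= eps**2
    result = inside | on_edge
    result[~np.isfinite(x) | ~np.isfinite(y)] = False
    return result


def point_in_polygon(point, polygon: EyeAOI) -> bool:
    """Scalar convenience wrapper around :func:`points_in_polygon`."""
    return bool(points_in_polygon(np.asarray(point, dtype=float).reshape(1, 2), polygon)[0])
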