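"""Optode digitization handling: reading, rigid alignment, templating, correction.

A *cap* is one digitization session: an ordered list of labeled 3D points
(anatomical landmarks first, then sources, then detectors) recorded with a
tracked stylus, in centimeters.  Digitizations are noisy — a participant may
move, or the experimenter may digitize the wrong point — so caps of one size
are mutually aligned (Kabsch) to build a consensus *template*, and individual
caps are then corrected against that template by replacing implausible points.

All coordinates are centimeters internally; the ``digpts.txt`` export is
millimeters (the convention of downstream anatomy tools).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Cap",
    "Template",
    "RigidTransform",
    "CorrectionReport",
    "LayoutSpec",
    "read_polhemus",
    "write_polhemus",
    "kabsch_align",
    "build_template",
    "threestep_alignment",
    "iterative_alignment",
    "headwise_alignment",
    "save_digpts",
    "read_digpts",
]

CM_PER_INCH = 2.54

ROLE_LANDMARK = "landmark"
ROLE_SOURCE = "source"
ROLE_DETECTOR = "detector"
_ROLE_ORDER = (ROLE_LANDMARK, ROLE_SOURCE, ROLE_DETECTOR)

#: default landmark labels, Homer digpts convention order
DEFAULT_LANDMARK_LABELS = ("nz", "iz", "ar", "al", "cz")


class LayoutMismatchError(ValueError):
    """Point count in a file does not match the declared layout."""


class DigitizationParseError(ValueError):
    """A digitization file could not be parsed."""


class UnderdeterminedAlignmentError(ValueError):
    """Fewer than 3 non-collinear correspondence points."""


class NoConsensusError(ValueError):
    """No cap matches any other within the template threshold."""

    def __init__(self, message: str, pairwise_distances: np.ndarray):
        super().__init__(message)
        self.pairwise_distances = pairwise_distances


class DegenerateCapError(ValueError):
    """Too few points survive correction to define an alignment."""


@dataclass
class LayoutSpec:
    """Declared structure of a Polhemus export: point counts per role and unit."""

    n_landmarks: int
    n_sources: int
    n_detectors: int
    unit: str = "cm"  # "cm" or "in"
    landmark_labels: Sequence[str] | None = None

    @property
    def n_points(self) -> int:
        return self.n_landmarks + self.n_sources + self.n_detectors

    def roles(self) -> list[str]:
        return (
            [ROLE_LANDMARK] * self.n_landmarks
            + [ROLE_SOURCE] * self.n_sources
            + [ROLE_DETECTOR] * self.n_detectors
        )

    def labels(self) -> list[str]:
        lm = list(self.landmark_labels or ())
        if not lm:
            defaults = list(DEFAULT_LANDMARK_LABELS)
            lm = [
                defaults[i] if i < len(defaults) else f"l{i + 1}"
                for i in range(self.n_landmarks)
            ]
        if len(lm) != self.n_landmarks:
            raise ValueError("landmark_labels length must equal n_landmarks")
        return (
            lm
            + [f"s{i + 1}" for i in range(self.n_sources)]
            + [f"d{i + 1}" for i in range(self.n_detectors)]
        )


@dataclass
class Cap:
    """One digitization: ordered labeled 3D points in cm.

    Points are stored landmarks-first, then sources, then detectors.
    ``replaced_mask`` marks points whose value came from a template rather
    than the measurement.
    """

    cap_id: str
    cap_size_cm: float
    points: np.ndarray  # (n, 3) cm
    roles: list[str]
    labels: list[str]
    replaced_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")
        n = len(self.points)
        if len(self.roles) != n or len(self.labels) != n:
            raise ValueError("roles/labels length must equal point count")
        order = [_ROLE_ORDER.index(r) for r in self.roles]
        if any(a > b for a, b in zip(order, order[1:])):
            raise ValueError("points must be ordered landmark, source, detector")
        if self.replaced_mask is None:
            self.replaced_mask = np.zeros(n, dtype=bool)
        else:
            self.replaced_mask = np.asarray(self.replaced_mask, dtype=bool)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def copy(self) -> "Cap":
        return replace(
            self, points=self.points.copy(), roles=list(self.roles),
            labels=list(self.labels), replaced_mask=self.replaced_mask.copy(),
        )


@dataclass
class Template:
    """Per-cap-size consensus cap: pointwise mean of mutually aligned caps."""

    cap_size_cm: float
    points: np.ndarray
    roles: list[str]
    labels: list[str]
    n_contributing: int
    threshold_cm: float
    reference_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.n_contributing < 1:
            raise ValueError("n_contributing must be >= 1")

    def as_cap(self, cap_id: str = "template") -> Cap:
        return Cap(cap_id, self.cap_size_cm, self.points.copy(),
                   list(self.roles), list(self.labels))


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class CorrectionReport:
    """Outcome of a point-replacement correction pass sequence."""

    thresholds_cm: list[float]
    distances_cm: np.ndarray  # final per-point 3D distance to template
    replaced_indices: np.ndarray
    proportion_replaced: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion_replaced <= 1.0:
            raise ValueError("proportion_replaced must lie in [0, 1]")


# ---------------------------------------------------------------------------
# I/O


def read_polhemus(path: str | Path, layout: LayoutSpec,
                  cap_id: str | None = None, cap_size_cm: float = 0.0) -> Cap:
    """Read a Polhemus ASCII export: one 3D point per row, whitespace separated.

    Roles are assigned positionally from ``layout``; coordinates declared in
    inches are converted to cm.
    """
    path = Path(path)
    rows: list[list[float]] = []
    for ln_no, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[,\s]+", line)
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise DigitizationParseError(
                f"{path}:{ln_no}: non-numeric row {line!r}") from exc
        if len(vals) != 3:
            raise DigitizationParseError(
                f"{path}:{ln_no}: expected 3 coordinates, got {len(vals)}")
        rows.append(vals)
    if not rows:
        raise DigitizationParseError(f"{path}: no coordinate rows found")
    if len(rows) != layout.n_points:
        raise LayoutMismatchError(
            f"{path}: {len(rows)} rows but layout declares {layout.n_points}")
    pts = np.asarray(rows, dtype=float)
    if layout.unit == "in":
        pts = pts * CM_PER_INCH
    elif layout.unit != "cm":
        raise ValueError(f"unknown unit {layout.unit!r}")
    return Cap(cap_id or path.stem, cap_size_cm, pts, layout.roles(),
               layout.labels())


def write_polhemus(cap: Cap, path: str | Path) -> Path:
    """Write a cap back to the one-point-per-row ASCII dialect (cm)."""
    path = Path(path)
    lines = [" ".join(f"{v:.6f}" for v in p) for p in cap.points]
    path.write_text("\n".join(lines) + "\n")
    return path


def save_digpts(cap: Cap, out_dir: str | Path,
                label_map: dict[str, str] | None = None) -> Path:
    """Export a cap as ``<out_dir>/<cap_id>/digpts.txt`` in mm.

    Format: one ``label: x y z`` line per point, landmarks then sources then
    detectors, coordinates converted cm -> mm.
    """
    out_dir = Path(out_dir) / cap.cap_id
    out_dir.mkdir(parents=True, exist_ok=True)
    label_map = label_map or {}
    lines = []
    for label, pt in zip(cap.labels, cap.points):
        if not label:
            raise ValueError("all points must be labeled for digpts export")
        mm = pt * 10.0
        lines.append(f"{label_map.get(label, label)}: "
                     f"{mm[0]:.6f} {mm[1]:.6f} {mm[2]:.6f}")
    out = out_dir / "digpts.txt"
    out.write_text("\n".join(lines) + "\n")
    return out


def read_digpts(path: str | Path, cap_size_cm: float = 0.0) -> Cap:
    """Read a digpts.txt file back into a Cap (mm -> cm)."""
    path = Path(path)
    labels: list[str] = []
    pts: list[list[float]] = []
    for ln_no, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        m = re.match(r"^(\S+):\s+(\S+)\s+(\S+)\s+(\S+)$", line)
        if not m:
            raise DigitizationParseError(f"{path}:{ln_no}: bad digpts line")
        labels.append(m.group(1))
        pts.append([float(m.group(i)) for i in (2, 3, 4)])
    if not pts:
        raise DigitizationParseError(f"{path}: empty digpts file")
    roles = []
    for lab in labels:
        if re.match(r"^s\d+$", lab):
            roles.append(ROLE_SOURCE)
        elif re.match(r"^d\d+$", lab):
            roles.append(ROLE_DETECTOR)
        else:
            roles.append(ROLE_LANDMARK)
    return Cap(Path(path).parent.name or path.stem, cap_size_cm,
               np.asarray(pts) / 10.0, roles, labels)


# ---------------------------------------------------------------------------
# Alignment


def _check_noncollinear(pts: np.ndarray) -> None:
    if len(pts) < 3:
        raise UnderdeterminedAlignmentError(
            f"need >= 3 correspondence points, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise UnderdeterminedAlignmentError(
            "correspondence points are collinear")


def kabsch_align(cap: Cap, reference: Cap | Template,
                 point_subset: np.ndarray | None = None,
                 ) -> tuple[RigidTransform, Cap, np.ndarray]:
    """Rigidly align ``cap`` to ``reference`` by the Kabsch algorithm.

    The optimal proper rotation minimizing RMSD over the correspondence
    subset is found by SVD of the cross-covariance; a reflection is
    suppressed by flipping the sign of the smallest singular vector.
    Correspondence is positional (caps share a fixed layout).

    Returns the recovered transform, the fully transformed cap, and the
    per-point 3D distances (all points) to the reference.
    """
    ref_pts = reference.points
    if cap.n_points != len(ref_pts):
        raise LayoutMismatchError(
            f"cap has {cap.n_points} points, reference {len(ref_pts)}")
    idx = (np.arange(cap.n_points) if point_subset is None
           else np.asarray(point_subset, dtype=int))
    p = cap.points[idx]
    q = ref_pts[idx]
    _check_noncollinear(p)
    cp, cq = p.mean(axis=0), q.mean(axis=0)
    h = (p - cp).T @ (q - cq)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cq - rot @ cp
    tf = RigidTransform(rot, trans)
    aligned = cap.copy()
    aligned.points = tf.apply(cap.points)
    dists = np.linalg.norm(aligned.points - ref_pts, axis=1)
    return tf, aligned, dists


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean squared deviation between corresponded point sets."""
    return float(np.sqrt(np.mean(np.sum((np.asarray(a) - np.asarray(b)) ** 2,
                                        axis=1))))


# ---------------------------------------------------------------------------
# Templates


def build_template(caps: Sequence[Cap], threshold_cm: float) -> Template:
    """Build a consensus template from caps of one size.

    Every cap is Kabsch-aligned to every other; a pair *matches* when no
    aligned point exceeds ``threshold_cm`` from its counterpart.  The cap
    with the most matches becomes the reference (ties broken by lowest mean
    distance to its matches, then by cap_id), and the template is the
    pointwise 3D mean over the reference and its matches after alignment to
    the reference.
    """
    if len(caps) < 2:
        raise ValueError("need >= 2 caps to build a template")
    if threshold_cm <= 0:
        raise ValueError("threshold_cm must be positive")
    n = len(caps)
    maxdist = np.full((n, n), np.nan)
    aligned_pts: dict[tuple[int, int], np.ndarray] = {}
    for j in range(n):  # j = candidate reference
        for i in range(n):
            if i == j:
                continue
            _, ali, dists = kabsch_align(caps[i], caps[j])
            maxdist[i, j] = dists.max()
            aligned_pts[(i, j)] = ali.points
    matches = [
        [i for i in range(n) if i != j and maxdist[i, j] <= threshold_cm]
        for j in range(n)
    ]
    counts = np.array([len(m) for m in matches])
    if counts.max() == 0:
        raise NoConsensusError(
            "no cap matches any other within "
            f"{threshold_cm} cm (see pairwise_distances)", maxdist)

    def tie_key(j: int) -> tuple[float, str]:
        mean_d = float(np.mean([maxdist[i, j] for i in matches[j]]))
        return (mean_d, caps[j].cap_id)

    best = min((j for j in range(n) if counts[j] == counts.max()), key=tie_key)
    stack = [caps[best].points] + [aligned_pts[(i, best)] for i in matches[best]]
    mean_pts = np.mean(np.stack(stack), axis=0)
    return Template(
        cap_size_cm=caps[best].cap_size_cm, points=mean_pts,
        roles=list(caps[best].roles), labels=list(caps[best].labels),
        n_contributing=1 + counts[best], threshold_cm=threshold_cm,
        reference_id=caps[best].cap_id,
    )


# ---------------------------------------------------------------------------
# Correction


def _finalize_correction(cap: Cap, template: Template,
                         retained: np.ndarray, thresholds: list[float],
                         ) -> tuple[Cap, CorrectionReport]:
    """Final alignment on retained points; dropped points take template values."""
    subset = np.flatnonzero(retained)
    try:
        _, aligned, dists = kabsch_align(cap, template, subset)
    except UnderdeterminedAlignmentError as exc:
        raise DegenerateCapError(
            f"cap {cap.cap_id}: only {retained.sum()} usable points remain"
        ) from exc
    corrected = aligned
    dropped = ~retained
    corrected.points[dropped] = template.points[dropped]
    corrected.replaced_mask = corrected.replaced_mask | dropped
    dists = np.linalg.norm(corrected.points - template.points, axis=1)
    report = CorrectionReport(
        thresholds_cm=list(thresholds), distances_cm=dists,
        replaced_indices=np.flatnonzero(dropped),
        proportion_replaced=float(dropped.mean()),
    )
    return corrected, report


def threestep_alignment(cap: Cap, template: Template,
                        d1: float, d2: float, d3: float,
                        ) -> tuple[Cap, CorrectionReport]:
    """Three sequential threshold passes against the template.

    Each pass aligns on the currently retained points, drops retained points
    whose 3D distance to the template exceeds the pass threshold (strict >),
    and re-aligns without them.  After the third pass, dropped points are
    replaced with the template's points in the final aligned frame; the
    output is co-registered to the template.
    """
    if not (d1 >= d2 >= d3 > 0):
        raise ValueError("thresholds must satisfy d1 >= d2 >= d3 > 0")
    retained = np.ones(cap.n_points, dtype=bool)
    for dk in (d1, d2, d3):
        subset = np.flatnonzero(retained)
        try:
            _, _, dists = kabsch_align(cap, template, subset)
        except UnderdeterminedAlignmentError as exc:
            raise DegenerateCapError(
                f"cap {cap.cap_id}: too few points before the "
                f"{dk} cm pass") from exc
        retained &= ~(retained & (dists > dk))
    return _finalize_correction(cap, template, retained, [d1, d2, d3])


def iterative_alignment(cap: Cap, template: Template,
                        max_prop_replaced: float,
                        start_cm: float = 20.0, step_cm: float = 1.0,
                        settle_cm: float = 0.5,
                        ) -> tuple[Cap, CorrectionReport]:
    """Decrementing-threshold correction.

    The threshold starts at ``start_cm`` (20 cm) and shrinks by ``step_cm``
    (1 cm) per pass, aligning and dropping out-of-threshold points each
    pass.  Iteration stops when dropping more points would push the replaced
    proportion past ``max_prop_replaced``, or when every retained point lies
    within ``settle_cm`` (0.5 cm) of the template, or when the threshold
    would fall below 1 cm.
    """
    if not 0 < max_prop_replaced <= 1:
        raise ValueError("max_prop_replaced must be in (0, 1]")
    retained = np.ones(cap.n_points, dtype=bool)
    used: list[float] = []
    thr = start_cm
    while thr >= 1.0:
        subset = np.flatnonzero(retained)
        try:
            _, _, dists = kabsch_align(cap, template, subset)
        except UnderdeterminedAlignmentError as exc:
            raise DegenerateCapError(
                f"cap {cap.cap_id}: too few points at the {thr} cm pass"
            ) from exc
        if np.all(dists[retained] <= settle_cm):
            break
        candidates = retained & (dists > thr)
        prop_after = ((~retained) | candidates).mean()
        if prop_after > max_prop_replaced:
            break
        used.append(thr)
        retained &= ~candidates
        thr -= step_cm
    return _finalize_correction(cap, template, retained, used)


def headwise_alignment(caps: Sequence[Cap], template: Template,
                       threshold_cm: float,
                       ) -> list[tuple[Cap, bool]]:
    """Whole-cap accept/replace against the template.

    Each cap is aligned to the template; if its mean per-point 3D distance
    exceeds ``threshold_cm`` the entire cap is replaced by the template,
    otherwise the aligned cap is kept unmodified.  Returns ``(cap,
    replaced)`` pairs.
    """
    if threshold_cm <= 0:
        raise ValueError("threshold_cm must be positive")
    out: list[tuple[Cap, bool]] = []
    for cap in caps:
        _, aligned, dists = kabsch_align(cap, template)
        if float(dists.mean()) > threshold_cm:
            repl = template.as_cap(cap.cap_id)
            repl.cap_size_cm = cap.cap_size_cm
            repl.replaced_mask = np.ones(repl.n_points, dtype=bool)
            out.append((repl, True))
        else:
            out.append((aligned, False))
    return out
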