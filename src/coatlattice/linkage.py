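"""Neighbor relative-orientation classification of ARF1-dimer linkages.

Every inter-stripe contact of the coat is bridged by a C2-symmetric ARF1
dimer.  Which end of each arch faces the contact (the beta3 end at body +x
or the delta end at body -x) depends on the stripe direction, so a lateral
neighbor pair falls into one of three classes:

* ``bd`` — heterotypic beta3-ARF1dimer-delta (parallel stripes),
* ``bb`` — homotypic beta3-ARF1dimer-beta3 (antiparallel),
* ``dd`` — homotypic delta-ARF1dimer-delta (antiparallel).

Classification needs only the two poses: the side of each member is the
sign of the inter-member displacement along its own body x axis, and
parallel vs antiparallel is the in-plane angle (rotation of the neighbor's
body x expressed in the member's frame, projected onto its xy plane) being
below or above 90 degrees.  Homotypic contacts are subsequently recentred
on the ARF1:ARF1 interface and collapsed to one C2 representative.

On a closed tube the six cyclic stripe boundaries force an exact balance:
every homotypic beta3-beta3 boundary is matched by a delta-delta boundary
(direction-bit transitions around a cycle alternate), which is the census
``balance_statistic``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import NotALateralContactError, StaleLinkageError
from .geometry import (
    Pose,
    eulers_to_matrices,
    fit_cylinder,
    matrix_to_euler,
    pose_from_row,
    relative_pose,
    table_positions,
    to_tube_frame,
)
from .lattice import LatticeReport, find_neighbors, trace_stripes
from .synthetic import ARF1_BODY_OFFSETS

#: displacement-dominance margin below which a contact is flagged ambiguous
AMBIGUITY_MARGIN = 0.05


@dataclass(frozen=True)
class LinkageRecord:
    """One classified AP3-ARF1dimer-AP3 inter-stripe contact."""

    id_a: int
    id_b: int
    side_a: str  # "b3" or "d"
    side_b: str
    link_class: str  # "bb", "bd" or "dd"
    parallel: bool
    inplane_angle_deg: float
    confidence: float
    ambiguous: bool = False

    def __post_init__(self):
        if not self.id_a < self.id_b:
            raise ValueError("LinkageRecord requires id_a < id_b")
        expected = "".join(sorted(s[0] for s in (self.side_a, self.side_b)))
        if self.link_class != expected:
            raise ValueError(
                f"class {self.link_class!r} inconsistent with sides "
                f"({self.side_a}, {self.side_b})"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")

    @property
    def homotypic(self) -> bool:
        return self.side_a == self.side_b


@dataclass(frozen=True)
class LinkageCensus:
    """Aggregate linkage statistics for one tube."""

    n_records: int
    counts: dict
    counts_interior: dict
    fraction_parallel: float
    n_interior: int
    boundary_classes: dict  # "s|t" stripe-label pair -> majority class
    balance_statistic: int  # bb boundaries minus dd boundaries

    def to_dict(self) -> dict:
        return asdict(self)


def _side(d_along_x: float) -> str:
    return "b3" if d_along_x > 0 else "d"


def classify_linkage(a: Pose, b: Pose) -> LinkageRecord:
    """Classify one lateral neighbor pair from relative position + orientation.

    The pair must be a lateral (inter-stripe) contact: in ``a``'s body frame
    the displacement must be dominated by the x (circumferential arch)
    component, otherwise :class:`NotALateralContactError` is raised.  A pair
    whose x and y displacement magnitudes agree within 5% is classified but
    flagged ambiguous.  Symmetric: the (unordered) result is independent of
    argument order.
    """
    if a.particle_id > b.particle_id:
        a, b = b, a
    d_ab, rel = relative_pose(a, b)
    d_ba, _ = relative_pose(b, a)
    ax, ay = abs(d_ab[0]), abs(d_ab[1])
    if ax <= ay:
        raise NotALateralContactError(
            f"pair ({a.particle_id}, {b.particle_id}) is axial: "
            f"|dx| = {ax:.1f} <= |dy| = {ay:.1f} A"
        )
    ambiguous = (ax - ay) < AMBIGUITY_MARGIN * ax
    side_a = _side(float(d_ab[0]))
    side_b = _side(float(d_ba[0]))
    # in-plane angle of b's body x axis in a's xy plane
    angle = float(np.rad2deg(np.arctan2(rel[1, 0], rel[0, 0])))
    parallel = abs(angle) < 90.0
    confidence = abs(abs(angle) - 90.0) / 90.0
    link_class = "".join(sorted(s[0] for s in (side_a, side_b)))
    return LinkageRecord(
        id_a=a.particle_id,
        id_b=b.particle_id,
        side_a=side_a,
        side_b=side_b,
        link_class=link_class,
        parallel=parallel,
        inplane_angle_deg=angle,
        confidence=confidence,
        ambiguous=ambiguous,
    )


def linkage_census(
    table: pd.DataFrame,
    report: LatticeReport,
    *,
    tol_frac: float = 0.3,
) -> tuple:
    """Classify every lateral neighbor pair of a tube and aggregate a census.

    Lateral pairs are those whose unrolled displacement integer-indexes to
    +-g1 against the (g1, g2) generator basis with residual below
    ``tol_frac * min(|g1|, |g2|)`` — indexing against the full basis keeps
    the g2 +- g1 displacement shells (which at the preset geometry lie only
    |g2| away from the g1 cluster) from leaking in under noise.  Tube-end
    particles (fewer than two lateral contacts) are excluded from the
    per-boundary majority vote and the balance statistic; raw class counts
    cover all records.  Returns ``(records, census)``.
    """
    fit = fit_cylinder(table_positions(table))
    framed = to_tube_frame(table, fit)
    radius = fit.radius
    g1 = np.array([report.g1_du_A, report.g1_dz_A])
    g2 = np.array([report.g2_du_A, report.g2_dz_A])
    tol = tol_frac * min(np.linalg.norm(g1), np.linalg.norm(g2))
    pairs = find_neighbors(framed, np.linalg.norm(g1) + np.linalg.norm(g2), radius)

    poses = {int(r["particle_id"]): pose_from_row(r) for _, r in framed.iterrows()}
    G = np.stack([g1, g2], axis=1)
    lateral = []
    contact_count: dict = {}
    for p in pairs:
        d = np.array([p.du_A, p.dz_A])
        mn = np.rint(np.linalg.solve(G, d))
        if (
            tuple(np.abs(mn)) == (1.0, 0.0)
            and np.linalg.norm(d - G @ mn) < tol
        ):
            lateral.append(p)
            contact_count[p.id_a] = contact_count.get(p.id_a, 0) + 1
            contact_count[p.id_b] = contact_count.get(p.id_b, 0) + 1

    stripe_labels = trace_stripes(framed, g2, radius_A=radius)
    label_of = {
        int(pid): int(lab)
        for pid, lab in zip(framed["particle_id"].to_numpy(), stripe_labels)
    }

    records, interiors, boundaries = [], [], []
    seen = set()
    for p in lateral:
        key = (p.id_a, p.id_b)
        if key in seen:
            continue
        seen.add(key)
        rec = classify_linkage(poses[p.id_a], poses[p.id_b])
        records.append(rec)
        interior = contact_count[p.id_a] >= 2 and contact_count[p.id_b] >= 2
        interiors.append(interior)
        sa, sb = sorted((label_of[p.id_a], label_of[p.id_b]))
        boundaries.append(f"{sa}|{sb}")

    counts = {"bb": 0, "bd": 0, "dd": 0}
    counts_interior = {"bb": 0, "bd": 0, "dd": 0}
    per_boundary: dict = {}
    n_par = 0
    for rec, interior, bkey in zip(records, interiors, boundaries):
        counts[rec.link_class] += 1
        n_par += rec.parallel
        if interior:
            counts_interior[rec.link_class] += 1
            per_boundary.setdefault(bkey, []).append(rec.link_class)
    boundary_classes = {
        bkey: max(set(classes), key=classes.count)
        for bkey, classes in sorted(per_boundary.items())
    }
    balance = sum(c == "bb" for c in boundary_classes.values()) - sum(
        c == "dd" for c in boundary_classes.values()
    )
    census = LinkageCensus(
        n_records=len(records),
        counts=counts,
        counts_interior=counts_interior,
        fraction_parallel=(n_par / len(records)) if records else 0.0,
        n_interior=int(sum(interiors)),
        boundary_classes=boundary_classes,
        balance_statistic=int(balance),
    )
    return records, census


def recenter_on_interface(
    record: LinkageRecord,
    table: pd.DataFrame,
    *,
    offsets: dict = ARF1_BODY_OFFSETS,
    max_separation_A: float | None = None,
    tube_axis=(0.0, 0.0, 1.0),
    interface_id: int = -1,
) -> Pose:
    """Rotate-then-shift a linkage onto its ARF1:ARF1 interface.

    The interface position is the midpoint of the two members' contact-
    facing ARF1 sites (body-frame ``offsets`` applied to each member's
    pose); the interface frame takes z from the mean member normal and x
    from the inter-member direction orthogonalized against z.  Homotypic
    interfaces are collapsed to one C2 representative via
    :func:`c2_canonicalize`.  Raises :class:`StaleLinkageError` when the
    members sit farther apart than ``max_separation_A``.
    """
    sub = table.set_index("particle_id")
    row_a = sub.loc[record.id_a]
    row_b = sub.loc[record.id_b]
    pa = np.array([row_a["x_A"], row_a["y_A"], row_a["z_A"]], dtype=float)
    pb = np.array([row_b["x_A"], row_b["y_A"], row_b["z_A"]], dtype=float)
    sep = float(np.linalg.norm(pb - pa))
    if max_separation_A is not None and sep > max_separation_A:
        raise StaleLinkageError(
            f"members {record.id_a}, {record.id_b} are {sep:.0f} A apart "
            f"(> {max_separation_A:.0f} A)"
        )
    Ra, Rb = eulers_to_matrices(
        np.array(
            [
                [row_a["rot_deg"], row_a["tilt_deg"], row_a["psi_deg"]],
                [row_b["rot_deg"], row_b["tilt_deg"], row_b["psi_deg"]],
            ]
        )
    )
    site_a = pa + Ra @ np.asarray(offsets[record.side_a], dtype=float)
    site_b = pb + Rb @ np.asarray(offsets[record.side_b], dtype=float)
    position = 0.5 * (site_a + site_b)

    z = Ra[:, 2] + Rb[:, 2]
    z = z / np.linalg.norm(z)
    x = pb - pa
    x = x - np.dot(x, z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    pose = Pose(
        particle_id=interface_id,
        position=position,
        euler_deg=matrix_to_euler(np.stack([x, y, z], axis=1)),
        tomo_id=str(row_a.get("tomo_id", "")),
        tube_id=str(row_a.get("tube_id", "")),
        score=record.confidence,
    )
    if record.homotypic:
        pose = c2_canonicalize(pose, tube_axis=tube_axis)
    return pose


def c2_canonicalize(pose: Pose, tube_axis=(0.0, 0.0, 1.0)) -> Pose:
    """Collapse the two C2-equivalent interface orientations to one.

    The dyad is the interface body x axis; the two orbit members differ by
    a 180-degree rotation about it (y, z negated).  The representative is
    the one whose body y axis has positive dot with the tube axis, ties
    broken by the global +z, then +x directions.  Idempotent and constant
    on the C2 orbit.
    """
    R = pose.rotation
    y = R[:, 1]
    for ref in (np.asarray(tube_axis, float), np.array([0.0, 0.0, 1.0]),
                np.array([1.0, 0.0, 0.0])):
        d = float(np.dot(y, ref))
        if abs(d) > 1e-9:
            if d > 0:
                return pose
            flipped = R @ np.diag([1.0, -1.0, -1.0])
            return Pose(
                particle_id=pose.particle_id,
                position=pose.position,
                euler_deg=matrix_to_euler(flipped),
                tomo_id=pose.tomo_id,
                tube_id=pose.tube_id,
                score=pose.score,
            )
    return pose


def recenter_all(
    records,
    table: pd.DataFrame,
    *,
    link_class: str | None = None,
    offsets: dict = ARF1_BODY_OFFSETS,
    max_separation_A: float | None = None,
    tube_axis=(0.0, 0.0, 1.0),
) -> pd.DataFrame:
    """Recentre every (optionally class-filtered) linkage; return a table.

    The output is a canonical particle table of interface poses with extra
    ``link_class``, ``id_a``, ``id_b`` and ``parallel`` columns; interface
    particle ids are sequential.
    """
    rows = []
    k = 0
    for rec in records:
        if link_class is not None and rec.link_class != link_class:
            continue
        pose = recenter_on_interface(
            rec,
            table,
            offsets=offsets,
            max_separation_A=max_separation_A,
            tube_axis=tube_axis,
            interface_id=k,
        )
        rows.append(
            {
                "particle_id": k,
                "tomo_id": pose.tomo_id,
                "tube_id": pose.tube_id,
                "x_A": pose.position[0],
                "y_A": pose.position[1],
                "z_A": pose.position[2],
                "rot_deg": pose.euler_deg[0],
                "tilt_deg": pose.euler_deg[1],
                "psi_deg": pose.euler_deg[2],
                "score": pose.score,
                "link_class": rec.link_class,
                "id_a": rec.id_a,
                "id_b": rec.id_b,
                "parallel": rec.parallel,
            }
        )
        k += 1
    cols = [
        "particle_id", "tomo_id", "tube_id", "x_A", "y_A", "z_A",
        "rot_deg", "tilt_deg", "psi_deg", "score",
        "link_class", "id_a", "id_b", "parallel",
    ]
    return pd.DataFrame(rows, columns=cols)
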