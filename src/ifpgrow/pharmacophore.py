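"""Shared-feature pharmacophore model building and binary pose filtering.

From a set of pre-aligned protein-ligand complexes, ligand-side feature
points are extracted from the detected contacts (donor and acceptor heavy
atoms engaged in hydrogen bonds; aromatic ring centroids engaged in
stacking), clustered across complexes by single-linkage within a merge
radius, and clusters present in at least a retention fraction of the
complexes become model features.  A pose passes the filter only when it
satisfies EVERY feature (the filter is a binary gate; partial matches are
reported but never pass).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

from .chemio import MoleculeRecord, ReceptorStructure
from .interactions import ContactParams, assign_ligand_roles, detect_contacts

FEATURE_KINDS = ("donor", "acceptor", "aromatic")


@dataclass(frozen=True)
class PharmacophoreFeature:
    """One spatial feature: a sphere, plus a unit normal for aromatics."""

    kind: str
    center: tuple[float, float, float]
    radius: float
    occupancy: float
    normal: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("feature radius must be positive")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in (0, 1]")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass
class PharmacophoreModel:
    features: list[PharmacophoreFeature]
    retention: float
    n_complexes: int

    def __post_init__(self) -> None:
        for f in self.features:
            if f.occupancy < self.retention - 1e-12:
                raise ValueError(
                    "model feature occupancy below the retention threshold"
                )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "retention": self.retention,
            "n_complexes": self.n_complexes,
            "features": [
                {
                    "kind": f.kind,
                    "center": list(f.center),
                    "radius": f.radius,
                    "occupancy": f.occupancy,
                    "normal": None if f.normal is None else list(f.normal),
                }
                for f in self.features
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PharmacophoreModel":
        if isinstance(source, Path) or (
            "\n" not in str(source) and Path(str(source)).exists()
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        features = [
            PharmacophoreFeature(
                kind=f["kind"],
                center=tuple(f["center"]),
                radius=f["radius"],
                occupancy=f["occupancy"],
                normal=None if f.get("normal") is None else tuple(f["normal"]),
            )
            for f in payload["features"]
        ]
        return cls(features, payload["retention"], payload["n_complexes"])


@dataclass
class _FeaturePoint:
    kind: str
    xyz: np.ndarray
    complex_index: int
    normal: np.ndarray | None = None


def _extract_feature_points(
    receptor: ReceptorStructure,
    pose: MoleculeRecord,
    complex_index: int,
    params: ContactParams | None,
) -> list[_FeaturePoint]:
    contacts = detect_contacts(receptor, pose, params)
    roles = assign_ligand_roles(pose)
    coords = pose.coordinates()
    points: list[_FeaturePoint] = []
    ring_by_atoms = {tuple(r.atoms): r for r in roles.rings}
    for c in contacts:
        if c.channel == 3:  # protein donor -> the ligand acceptor atom
            idx = int(c.ligand_atoms[0])
            points.append(_FeaturePoint("acceptor", coords[idx], complex_index))
        elif c.channel == 4:  # protein acceptor -> the ligand donor atom
            idx = int(c.ligand_atoms[0])
            points.append(_FeaturePoint("donor", coords[idx], complex_index))
        elif c.channel in (1, 2):
            ring = ring_by_atoms.get(tuple(int(i) for i in c.ligand_atoms))
            if ring is not None:
                points.append(
                    _FeaturePoint(
                        "aromatic", ring.centroid, complex_index, ring.normal
                    )
                )
    return points


def build_model(
    complexes: list[tuple[ReceptorStructure, MoleculeRecord]],
    retention: float = 0.5,
    merge_radius: float = 1.5,
    contact_params: ContactParams | None = None,
    min_radius: float = 0.5,
) -> PharmacophoreModel:
    """Build the shared-feature model from pre-aligned complexes.

    A cluster's occupancy is the fraction of source complexes contributing
    at least one point to it; clusters with occupancy >= ``retention``
    become features.  Clustering is single-linkage within ``merge_radius``
    (order-independent); the feature center is the cluster centroid and its
    radius the cluster spread (floored at ``min_radius``).
    """
    if not complexes:
        raise ValueError("at least one complex is required")
    n = len(complexes)
    points: list[_FeaturePoint] = []
    for i, (receptor, pose) in enumerate(complexes):
        points.extend(_extract_feature_points(receptor, pose, i, contact_params))

    features: list[PharmacophoreFeature] = []
    for kind in FEATURE_KINDS:
        kind_pts = [p for p in points if p.kind == kind]
        if not kind_pts:
            continue
        xyz = np.array([p.xyz for p in kind_pts])
        if len(kind_pts) == 1:
            labels = np.array([1])
        else:
            labels = fcluster(
                linkage(pdist(xyz), method="single"),
                t=merge_radius,
                criterion="distance",
            )
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            occupancy = len({kind_pts[i].complex_index for i in idx}) / n
            if occupancy + 1e-12 < retention:
                continue
            center = xyz[idx].mean(axis=0)
            radius = max(
                min_radius,
                float(np.linalg.norm(xyz[idx] - center, axis=1).max()),
            )
            normal = None
            if kind == "aromatic":
                normals = []
                ref = kind_pts[idx[0]].normal
                for i in idx:
                    nrm = kind_pts[i].normal
                    normals.append(nrm if np.dot(nrm, ref) >= 0 else -nrm)
                normal = np.mean(normals, axis=0)
                normal = tuple(normal / np.linalg.norm(normal))
            features.append(
                PharmacophoreFeature(
                    kind=kind,
                    center=tuple(float(x) for x in center),
                    radius=radius,
                    occupancy=occupancy,
                    normal=normal,
                )
            )
    features.sort(key=lambda f: (f.kind, np.round(f.center, 3).tolist()))
    return PharmacophoreModel(features, retention, n)


def matches(
    model: PharmacophoreModel,
    pose: MoleculeRecord,
    tolerance: float = 1.0,
    angle_tolerance: float = 30.0,
) -> tuple[bool, list[dict]]:
    """Check a pose against every feature of the model (AND semantics).

    Returns (all features satisfied, per-feature report).  A feature is
    satisfied when a ligand point of the matching role lies within
    ``radius + tolerance`` of its center; aromatic features additionally
    require the ring-normal angle (folded to [0, 90]) within
    ``angle_tolerance`` degrees.
    """
    roles = assign_ligand_roles(pose)
    candidates = {
        "donor": [(d.xyz, None) for d in roles.donors],
        "acceptor": [(np.asarray(xyz), None) for _, xyz in roles.acceptors],
        "aromatic": [(r.centroid, r.normal) for r in roles.rings],
    }
    report = []
    ok = True
    for i, feat in enumerate(model.features):
        best_dist = np.inf
        satisfied = False
        for xyz, normal in candidates[feat.kind]:
            d = float(np.linalg.norm(xyz - feat.xyz))
            if d < best_dist:
                best_dist = d
            if d > feat.radius + tolerance:
                continue
            if feat.kind == "aromatic" and feat.normal is not None:
                cosv = abs(float(np.dot(normal, np.asarray(feat.normal))))
                angle = np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))
                if angle > angle_tolerance:
                    continue
            satisfied = True
        ok = ok and satisfied
        report.append(
            {
                "feature": i,
                "kind": feat.kind,
                "satisfied": satisfied,
                "best_distance": None if np.isinf(best_dist) else round(best_dist, 3),
            }
        )
    return ok, report


class PharmacophoreFilter(BaseEstimator):
    """Estimator facade: fit on aligned complexes, predict pass/fail for poses."""

    def __init__(
        self,
        retention: float = 0.5,
        merge_radius: float = 1.5,
        tolerance: float = 1.0,
        angle_tolerance: float = 30.0,
        contact_params: ContactParams | None = None,
    ):
        self.retention = retention
        self.merge_radius = merge_radius
        self.tolerance = tolerance
        self.angle_tolerance = angle_tolerance
        self.contact_params = contact_params

    def fit(self, complexes, y=None) -> "PharmacophoreFilter":
        self.model_ = build_model(
            complexes,
            retention=self.retention,
            merge_radius=self.merge_radius,
            contact_params=self.contact_params,
        )
        return self

    def predict(self, poses) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ValueError("PharmacophoreFilter is not fitted; call fit first")
        return np.array(
            [
                matches(self.model_, p, self.tolerance, self.angle_tolerance)[0]
                for p in poses
            ],
            dtype=bool,
        )

    def report(self, pose) -> list[dict]:
        return matches(self.model_, pose, self.tolerance, self.angle_tolerance)[1]
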