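"""Synthetic deformed-surface cohorts with known ground truth.

The generator emulates the computer-generated validation designs used for
surface-morphometry classifiers: copies of a single template surface carry
a 15-mm-wide protrusion or indentation at one of two fixed sites (stand-ins
for dorsolateral prefrontal and occipital cortex locations, called A and B
here), are placed at random rigid positions in space, and - in the
multi-individual design - additionally receive a smooth, subject-specific
radial perturbation standing in for normal anatomical variability.

All randomness is driven by :class:`numpy.random.SeedSequence` spawned from
the cohort seed, so datasets are bit-reproducible from ``(spec, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.special import sph_harm_y

from .icosphere import icosphere
from .mesh import TriangleMesh, write_mesh

__all__ = ["DeformationSpec", "CohortSpec", "SITE_DIRECTIONS", "make_template",
           "add_deformation", "rigid_place", "individual_variation",
           "make_cohort", "make_dataset", "make_covariates"]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _from_spherical(colat_deg: float, lon_deg: float) -> np.ndarray:
    th = np.deg2rad(colat_deg)
    ph = np.deg2rad(lon_deg)
    return np.array([np.cos(ph) * np.sin(th), np.sin(ph) * np.sin(th),
                     np.cos(th)])


#: The two deformation sites, fixed unit directions ~87 degrees of arc apart
#: (site A stands in for the DLPFC location, site B for the occipital one).
SITE_DIRECTIONS = {
    "A": _from_spherical(75.0, 15.0),
    "B": _from_spherical(80.0, 105.0),
}


@dataclass(frozen=True)
class DeformationSpec:
    """A single focal surface deformation.

    ``site`` is ``"A"``/``"B"`` or an explicit unit direction; ``width`` is
    the full angular footprint of the deformation measured on the surface
    (mm); ``polarity`` is ``"protrusion"`` (outward) or ``"indentation"``
    (inward); ``amplitude`` the peak radial displacement (mm).
    """

    site: object = "A"
    width: float = 15.0
    polarity: str = "protrusion"
    amplitude: float = 7.5

    def __post_init__(self):
        if self.width <= 0 or self.amplitude <= 0:
            raise ValueError("width and amplitude must be positive")
        if self.polarity not in ("protrusion", "indentation"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def direction(self) -> np.ndarray:
        if isinstance(self.site, str):
            return SITE_DIRECTIONS[self.site]
        return _unit(self.site)

    @property
    def sign(self) -> float:
        return 1.0 if self.polarity == "protrusion" else -1.0


def _random_smooth_field(directions: np.ndarray, degrees, rng) -> np.ndarray:
    """Random real linear combination of spherical harmonics, unit rms."""
    theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))
    phi = np.arctan2(directions[:, 1], directions[:, 0])
    out = np.zeros(len(directions))
    for ell in degrees:
        for m in range(0, ell + 1):
            y = sph_harm_y(ell, m, theta, phi)
            if m == 0:
                out += rng.normal() * y.real
            else:
                out += rng.normal() * np.sqrt(2) * y.real
                out += rng.normal() * np.sqrt(2) * y.imag
    rms = np.sqrt(np.mean(out ** 2))
    return out / max(rms, 1e-300)


def make_template(level: int = 4, radius: float = 80.0,
                  bumpiness: float = 3.0, seed: int | None = 0) -> TriangleMesh:
    """Brain-like star-shaped template: an icosphere of the given radius
    with a smooth low-order random radial perturbation (rms ``bumpiness``
    mm).  Level 4 at radius 80 mm has 2562 vertices and ~6 mm edges, well
    below the 15 mm deformation footprint."""
    if level < 0:
        raise ValueError("level must be >= 0")
    base = icosphere(level).mesh
    dirs = base.vertices
    r = np.full(base.n_vertices, float(radius))
    if bumpiness > 0:
        rng = np.random.default_rng(seed)
        r = r + bumpiness * _random_smooth_field(dirs, (2, 3, 4), rng)
    if np.any(r <= 0.2 * radius):
        raise ValueError("bumpiness too large: template would self-intersect")
    return TriangleMesh(dirs * r[:, None], base.faces, name=f"template{level}")


def add_deformation(mesh: TriangleMesh, spec: DeformationSpec,
                    center=None) -> TriangleMesh:
    """Superimpose a focal protrusion or indentation.

    Vertices within ``width/2`` (along the surface) of the site are moved
    radially away from ``center`` - which coincides with the outward normal
    direction for star-shaped surfaces - by the amplitude times a C1 cosine
    taper.  ``center`` defaults to the origin, where generated templates
    live; because it is a fixed reference (not recomputed from the deformed
    geometry) and the displacement is purely radial, applying the
    equal-amplitude opposite polarity restores the input exactly.
    """
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    rel = mesh.vertices - c
    mean_radius = float(np.linalg.norm(rel, axis=1).mean())
    if np.linalg.norm(mesh.centroid() - c) > 0.5 * mean_radius:
        raise ValueError(
            "reference center is far from the surface centroid; pass an "
            "explicit center for meshes positioned away from the origin")
    rad = np.linalg.norm(rel, axis=1)
    u = rel / rad[:, None]
    psi = np.arccos(np.clip(u @ spec.direction, -1.0, 1.0))
    # nominal radius from the far hemisphere only: those vertices are never
    # inside the support, so repeated deformations see the same scale (this
    # is what makes protrusion followed by indentation an exact inverse)
    far = psi > np.pi / 3.0
    r_nominal = float(np.mean(rad[far]))
    if spec.width / 2.0 >= r_nominal * np.pi / 3.0:
        raise ValueError("deformation width too large for this surface")
    geodesic = r_nominal * psi
    half = spec.width / 2.0
    profile = np.where(geodesic < half,
                       0.5 * (1.0 + np.cos(np.pi * geodesic / half)), 0.0)
    displacement = spec.sign * spec.amplitude * profile
    new_rad = rad + displacement
    if np.any(new_rad <= 0):
        raise ValueError("deformation amplitude causes self-intersection")
    return TriangleMesh(c + u * new_rad[:, None], mesh.faces, mesh.name)


def rigid_place(mesh: TriangleMesh, seed: int | None,
                max_translation: float = 20.0) -> TriangleMesh:
    """Random rigid placement: rotation uniform over SO(3) about the
    centroid plus a uniform translation of up to ``max_translation`` mm per
    axis.  ``seed=None`` is the reserved null seed and returns the mesh
    unchanged."""
    if seed is None:
        return mesh
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-max_translation, max_translation, size=3)
    c = mesh.centroid()
    return TriangleMesh((mesh.vertices - c) @ rot.T + c + t, mesh.faces,
                        mesh.name)


def individual_variation(mesh: TriangleMesh, amplitude: float = 2.0,
                         correlation_scale_deg: float = 30.0,
                         seed: int | None = 0) -> TriangleMesh:
    """Smooth subject-specific morphology: a correlated random radial field
    (spherical harmonics up to degree ~180/scale, unit rms, scaled to
    ``amplitude`` mm) added along the radial directions."""
    if amplitude == 0:
        return mesh
    max_degree = max(1, int(round(180.0 / correlation_scale_deg)))
    rng = np.random.default_rng(seed)
    c = mesh.centroid()
    rel = mesh.vertices - c
    rad = np.linalg.norm(rel, axis=1)
    u = rel / rad[:, None]
    fld = amplitude * _random_smooth_field(u, range(1, max_degree + 1), rng)
    new_rad = rad + fld
    if np.any(new_rad <= 0):
        raise ValueError("variation amplitude causes self-intersection")
    return TriangleMesh(c + u * new_rad[:, None], mesh.faces, mesh.name)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

_DEFAULT_CELLS = (("A", "protrusion"), ("A", "indentation"),
                  ("B", "protrusion"), ("B", "indentation"))


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``single_template`` reproduces the identical-copies design (one base
    surface, rigid placements only); ``multi_individual`` gives every
    subject its own smooth morphological variability before the deformation
    is added.
    """

    design: str = "single_template"
    n_per_cell: int = 10
    cells: tuple = _DEFAULT_CELLS
    rigid_placement: bool = True
    # Residual per-subject variability surviving spatial normalization to
    # the template (the surface measures live in template space, where
    # nonlinear warping has already absorbed gross anatomical differences;
    # what remains is sub-millimetre, smooth registration residual).
    variation_amplitude: float = 0.25
    variation_scale_deg: float = 30.0
    template_level: int = 4
    radius: float = 80.0
    bumpiness: float = 3.0
    width: float = 15.0
    amplitude: float = 7.5
    seed: int = 0

    def __post_init__(self):
        if self.design not in ("single_template", "multi_individual"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")


@dataclass(frozen=True)
class SyntheticCohort:
    """In-memory generated cohort: template + per-subject meshes + truth."""

    spec: CohortSpec
    template: TriangleMesh
    meshes: list          # TriangleMesh per subject
    manifest: pd.DataFrame  # id, cell, site, polarity, age, sex


def _cell_label(site, polarity) -> str:
    return f"{site}_{polarity}"


def make_covariates(n: int, seed: int | None = 0) -> pd.DataFrame:
    """Placeholder demographics: ages uniform in 20-50 years, sexes
    balanced (alternating M/F after a seeded shuffle)."""
    rng = np.random.default_rng(seed)
    ages = rng.uniform(20.0, 50.0, size=n)
    sexes = np.array(["M", "F"] * (n // 2 + 1))[:n]
    rng.shuffle(sexes)
    return pd.DataFrame({"age": ages, "sex": sexes})


def inject_age_effect(values: np.ndarray, ages: np.ndarray,
                      slope: float) -> np.ndarray:
    """Add a linear age effect (``slope`` per year, centered) to a feature,
    for exercising nuisance-covariate residualization."""
    ages = np.asarray(ages, dtype=float)
    return np.asarray(values, dtype=float) + slope * (ages - ages.mean())


def make_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the cohort in memory, bit-reproducibly from (spec, seed)."""
    root = np.random.SeedSequence(spec.seed)
    ss_template, ss_cov, ss_subjects = root.spawn(3)
    template = make_template(spec.template_level, spec.radius, spec.bumpiness,
                             seed=ss_template)
    n_total = spec.n_per_cell * len(spec.cells)
    cov = make_covariates(n_total, seed=ss_cov)
    subject_seeds = ss_subjects.spawn(n_total)

    meshes, rows = [], []
    idx = 0
    for site, polarity in spec.cells:
        dspec = DeformationSpec(site=site, width=spec.width,
                                polarity=polarity, amplitude=spec.amplitude)
        for k in range(spec.n_per_cell):
            ss_var, ss_place = subject_seeds[idx].spawn(2)
            base = template
            if spec.design == "multi_individual":
                base = individual_variation(base, spec.variation_amplitude,
                                            spec.variation_scale_deg,
                                            seed=ss_var)
            deformed = add_deformation(base, dspec)
            placed = rigid_place(deformed, seed=ss_place) \
                if spec.rigid_placement else deformed
            sid = f"s{idx:03d}"
            meshes.append(placed)
            rows.append({"id": sid, "cell": _cell_label(site, polarity),
                         "site": str(site), "polarity": polarity,
                         "age": cov.loc[idx, "age"], "sex": cov.loc[idx, "sex"]})
            idx += 1
    manifest = pd.DataFrame(rows)
    return SyntheticCohort(spec, template, meshes, manifest)


def make_dataset(spec: CohortSpec, outdir) -> Path:
    """Materialize a cohort on disk: meshes/ (OFF), template.off,
    manifest.csv, truth.json and spec.json."""
    cohort = make_cohort(spec)
    outdir = Path(outdir)
    (outdir / "meshes").mkdir(parents=True, exist_ok=True)
    write_mesh(cohort.template, outdir / "template.off")
    paths = []
    for sid, mesh in zip(cohort.manifest["id"], cohort.meshes):
        p = outdir / "meshes" / f"{sid}.off"
        write_mesh(mesh, p)
        paths.append(str(p.relative_to(outdir)))
    manifest = cohort.manifest.copy()
    manifest["mesh"] = paths
    manifest.to_csv(outdir / "manifest.csv", index=False)
    truth = dict(zip(cohort.manifest["id"], cohort.manifest["cell"]))
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    spec_dict = asdict(spec)
    spec_dict["cells"] = [list(c) for c in spec.cells]
    (outdir / "spec.json").write_text(json.dumps(spec_dict, indent=1, default=str))
    return outdir
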