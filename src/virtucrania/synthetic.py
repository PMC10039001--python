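"""Synthetic cranium-like specimens with known ground truth.

Every analysis stage of the package is exercised on specimens generated
here: a smoothly deformed ellipsoid "cranium" carrying 28 named
craniometric landmarks, an occipital patch of 5 fixed landmarks plus 150
surface semilandmarks, endocast shells of analytically known volume,
fragment pairs with recorded rigid motions, and binary characters evolved
on a known tree. All randomness is seeded and reproducible.

The template surface is parameterised over unit directions u:

    p(u) = rho(u) * (a*u_x, b*u_y, c*u_z)

with semi-axes (a, b, c) = (90, 70, 65) mm (anterior-posterior, lateral,
vertical; roughly adult-hominin proportions) and a smooth low-order radial
modulation rho. Mesh vertices and landmarks evaluate the same function, so
they stay mutually consistent. Population variation is applied as a
landmark-driven thin-plate-spline deformation of the whole specimen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .landmarks import LandmarkConfiguration, PairingTable
from .meshes import TriMesh, mesh_volume
from .procrustes import SimilarityTransform
from .tps import TPSModel, tps_fit, tps_warp
from .traits import MISSING, CharacterMatrix, PhyloTree

__all__ = [
    "Specimen",
    "CranialTemplate",
    "generate_template",
    "generate_population",
    "fragment_specimen",
    "generate_endocast",
    "simulate_characters",
    "FragmentPair",
    "DEFAULT_GROUPS",
]

SEMI_AXES = (90.0, 70.0, 65.0)  # mm; x anterior(+), y left(+), z superior(+)

# unit-sphere directions (before normalisation) of the 28 template landmarks;
# x anterior, y left, z superior
_LANDMARK_DIRECTIONS: dict[str, tuple[float, float, float]] = {
    # midline (8)
    "glabella": (1.0, 0.0, 0.10),
    "nasion": (1.0, 0.0, -0.05),
    "bregma": (0.20, 0.0, 1.0),
    "vertex": (0.0, 0.0, 1.0),
    "lambda": (-0.55, 0.0, 0.80),
    "opisthocranion": (-1.0, 0.0, 0.0),
    "inion": (-0.95, 0.0, -0.25),
    "opisthion": (-0.50, 0.0, -0.90),
    # bilateral pairs (10 x 2); left = +y
    "frontomalare_L": (0.90, 0.45, -0.10),
    "frontomalare_R": (0.90, -0.45, -0.10),
    "frontotemporale_L": (0.75, 0.60, 0.35),
    "frontotemporale_R": (0.75, -0.60, 0.35),
    "stephanion_L": (0.40, 0.50, 0.75),
    "stephanion_R": (0.40, -0.50, 0.75),
    "pterion_L": (0.55, 0.80, 0.20),
    "pterion_R": (0.55, -0.80, 0.20),
    "zygion_L": (0.50, 0.95, -0.30),
    "zygion_R": (0.50, -0.95, -0.30),
    "porion_L": (0.05, 1.0, -0.35),
    "porion_R": (0.05, -1.0, -0.35),
    "euryon_L": (-0.35, 1.0, 0.10),
    "euryon_R": (-0.35, -1.0, 0.10),
    "asterion_L": (-0.70, 0.60, -0.30),
    "asterion_R": (-0.70, -0.60, -0.30),
    "mastoidale_L": (-0.25, 0.80, -0.80),
    "mastoidale_R": (-0.25, -0.80, -0.80),
    "supramastoid_L": (-0.30, 0.95, -0.40),
    "supramastoid_R": (-0.30, -0.95, -0.40),
}

MIDLINE_NAMES = (
    "glabella",
    "nasion",
    "bregma",
    "vertex",
    "lambda",
    "opisthocranion",
    "inion",
    "opisthion",
)

BILATERAL_PAIRS = tuple(
    (f"{stem}_L", f"{stem}_R")
    for stem in (
        "frontomalare",
        "frontotemporale",
        "stephanion",
        "pterion",
        "zygion",
        "porion",
        "euryon",
        "asterion",
        "mastoidale",
        "supramastoid",
    )
)

PAIRING = PairingTable(pairs=BILATERAL_PAIRS, midline=MIDLINE_NAMES)

# anterior (frontal-facial, "FF") vs posterior (back, "BP") landmark split
FF_NAMES = (
    "glabella", "nasion", "bregma", "vertex",
    "frontomalare_L", "frontomalare_R",
    "frontotemporale_L", "frontotemporale_R",
    "stephanion_L", "stephanion_R",
    "pterion_L", "pterion_R",
    "zygion_L", "zygion_R",
    "porion_L", "porion_R",
)
BP_NAMES = (
    "lambda", "opisthocranion", "inion", "opisthion",
    "euryon_L", "euryon_R",
    "asterion_L", "asterion_R",
    "mastoidale_L", "mastoidale_R",
    "supramastoid_L", "supramastoid_R",
)

OCCIPITAL_FIXED = ("lambda", "inion", "opisthion", "asterion_L", "asterion_R")

# group structure loosely emulating four hominin groups: Middle Pleistocene
# humans, early Neanderthals, Wuermian "classic" Neanderthals, and a
# modern-like group. (offset_scale_mm, individual_sd_mm)
DEFAULT_GROUPS: dict[str, tuple[float, float]] = {
    "MPH": (6.0, 1.5),
    "ERN": (4.0, 1.5),
    "EWN": (8.0, 1.5),
    "MOD": (12.0, 1.5),
}


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


@dataclass
class CranialTemplate:
    """Deterministic synthetic cranium: mesh + landmarks + occipital patch."""

    mesh: TriMesh
    landmarks: LandmarkConfiguration
    occipital_fixed: LandmarkConfiguration
    occipital_semis: np.ndarray  # (150, 3), on the mesh surface
    occipital_faces: np.ndarray  # triangulation template over the 155 points
    semi_axes: tuple[float, float, float]
    bump_amplitude: float
    seed: int


@dataclass
class Specimen:
    """One synthetic individual, with the deformation that produced it."""

    specimen_id: str
    group: str
    mesh: TriMesh
    landmarks: LandmarkConfiguration
    occipital_semis: np.ndarray
    template: CranialTemplate
    deformation: TPSModel | None  # template -> specimen; None for the template itself


@dataclass
class FragmentPair:
    """Two disarticulated fragments with disjoint landmark name sets."""

    frag_a: LandmarkConfiguration
    frag_b: LandmarkConfiguration
    mesh_a: TriMesh | None = None
    mesh_b: TriMesh | None = None
    truth_transform_a: SimilarityTransform | None = None
    truth_transform_b: SimilarityTransform | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        shared = set(self.frag_a.landmark_names) & set(self.frag_b.landmark_names)
        if shared:
            raise ValueError(f"fragments share landmark names: {sorted(shared)}")
        if len(self.frag_a) < 4 or len(self.frag_b) < 4:
            raise ValueError("each fragment needs >= 4 landmarks")


def _radial_modulation(directions: np.ndarray, seed: int, amplitude: float) -> np.ndarray:
    """Smooth, bilaterally symmetric radial bump field rho(u).

    A small set of low-order separable harmonics in the direction
    components, with coefficients drawn once from the seed. Symmetric in y
    so the template is perfectly bilaterally symmetric.
    """
    if amplitude == 0.0:
        return np.ones(len(directions))
    rng = np.random.default_rng(seed)
    coeffs = rng.uniform(-1.0, 1.0, size=6)
    x, y, z = directions[:, 0], directions[:, 1], directions[:, 2]
    basis = np.stack(
        [
            np.sin(2.0 * x),
            np.cos(3.0 * z),
            np.sin(2.0 * x) * np.cos(2.0 * z),
            np.cos(2.0 * y),  # even in y: preserves bilateral symmetry
            np.sin(3.0 * z) * np.cos(1.0 * x),
            np.cos(4.0 * y) * np.sin(1.0 * z),
        ],
        axis=1,
    )
    field_vals = basis @ coeffs
    field_vals = field_vals / max(np.abs(field_vals).max(), 1e-12)
    return 1.0 + amplitude * field_vals


def _surface_points(directions: np.ndarray, seed: int, amplitude: float,
                    semi_axes=SEMI_AXES) -> np.ndarray:
    u = _unit(directions)
    rho = _radial_modulation(u, seed, amplitude)
    a, b, c = semi_axes
    return rho[:, None] * u * np.array([a, b, c])


def _fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic, roughly uniform unit directions (Fibonacci sphere)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _occipital_triangulation(points: np.ndarray) -> np.ndarray:
    """2D Delaunay template over the occipital patch, projected along the
    mean outward direction."""
    from scipy.spatial import Delaunay

    centre_dir = _unit(points.mean(axis=0))
    # local tangent frame
    ref = np.array([0.0, 0.0, 1.0])
    if abs(centre_dir @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(centre_dir, ref))
    e2 = np.cross(centre_dir, e1)
    uv = np.stack([points @ e1, points @ e2], axis=1)
    tri = Delaunay(uv)
    return np.asarray(tri.simplices, dtype=np.int64)


def generate_template(
    seed: int = 42,
    subdivisions: int = 3,
    bump_amplitude: float = 0.03,
    n_semis: int = 150,
) -> CranialTemplate:
    """Build the deterministic synthetic cranial template.

    ``bump_amplitude`` is the relative amplitude of the smooth radial
    modulation (0 gives the exact ellipsoid, useful for analytic volume
    oracles). The same seed always yields bit-identical output.
    """
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    directions = np.asarray(ico.vertices)
    vertices = _surface_points(directions, seed, bump_amplitude)
    mesh = TriMesh(vertices, np.asarray(ico.faces), validate=False)

    names = list(_LANDMARK_DIRECTIONS)
    lm_dirs = np.array([_LANDMARK_DIRECTIONS[n] for n in names])
    lm_coords = _surface_points(lm_dirs, seed, bump_amplitude)
    landmarks = LandmarkConfiguration(
        specimen_id="template",
        landmark_names=names,
        coords=lm_coords,
        pairing=PAIRING,
    )

    # occipital patch: 5 fixed + n_semis surface semilandmarks on the
    # posterior cap (analytic surface, then snapped to the mesh)
    occ_fixed = landmarks.subset(list(OCCIPITAL_FIXED))
    occ_fixed.pairing = None
    cand = _fibonacci_directions(3000)
    posterior = cand[cand[:, 0] < -0.35]
    semi_dirs = posterior[:n_semis]
    if len(semi_dirs) < n_semis:
        raise ValueError("not enough posterior directions for semilandmarks")
    semis = _surface_points(semi_dirs, seed, bump_amplitude)
    # snap to the triangulated surface so semis lie exactly on the mesh
    closest, _, _ = trimesh.proximity.closest_point_naive(mesh.as_trimesh(), semis)
    semis = np.asarray(closest)

    patch_points = np.vstack([occ_fixed.coords, semis])
    occ_faces = _occipital_triangulation(patch_points)

    return CranialTemplate(
        mesh=mesh,
        landmarks=landmarks,
        occipital_fixed=occ_fixed,
        occipital_semis=semis,
        occipital_faces=occ_faces,
        semi_axes=SEMI_AXES,
        bump_amplitude=bump_amplitude,
        seed=seed,
    )


def template_ellipsoid_volume_cc(template: CranialTemplate) -> float:
    """Analytic volume (cc) of the template's generating ellipsoid."""
    a, b, c = template.semi_axes
    return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


def _deform_specimen(
    template: CranialTemplate,
    displaced_landmarks: np.ndarray,
    specimen_id: str,
    group: str,
) -> Specimen:
    """Warp the whole template (mesh, landmarks, semis) through the TPS
    that carries the template landmarks onto their displaced positions."""
    model = tps_fit(template.landmarks.coords, displaced_landmarks)
    mesh = template.mesh.with_vertices(tps_warp(model, template.mesh.vertices))
    landmarks = template.landmarks.with_coords(
        displaced_landmarks, specimen_id=specimen_id
    )
    landmarks.group = group
    semis = tps_warp(model, template.occipital_semis)
    return Specimen(
        specimen_id=specimen_id,
        group=group,
        mesh=mesh,
        landmarks=landmarks,
        occipital_semis=semis,
        template=template,
        deformation=model,
    )


def generate_population(
    template: CranialTemplate,
    n: int = 20,
    groups: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[Specimen]:
    """Generate ``n`` individuals with group structure and known truth.

    Each group receives a fixed mean landmark displacement of the stated
    scale (mm); each individual adds isotropic Gaussian landmark noise of
    the group's SD (mm). The full specimen (mesh, landmarks, occipital
    semilandmarks) is deformed consistently by one TPS per individual, so
    ground truth (group labels, deformations) is exactly known.
    """
    if n < 2:
        raise ValueError("population needs n >= 2")
    groups = groups or DEFAULT_GROUPS
    rng = np.random.default_rng(seed)
    group_names = list(groups)
    # fixed per-group mean displacement fields
    group_offsets = {}
    for g in group_names:
        scale, _ = groups[g]
        direction = rng.standard_normal(template.landmarks.coords.shape)
        # normalise so the mean per-landmark displacement equals `scale` mm
        group_offsets[g] = scale * direction / np.linalg.norm(direction, axis=1).mean()

    specimens = []
    for i in range(n):
        g = group_names[i % len(group_names)]
        _, sd = groups[g]
        noise = rng.normal(0.0, sd, size=template.landmarks.coords.shape)
        displaced = template.landmarks.coords + group_offsets[g] + noise
        specimens.append(
            _deform_specimen(template, displaced, f"{g}_{i:02d}", g)
        )
    return specimens


def specimen_from_template(template: CranialTemplate, specimen_id: str = "template",
                           group: str = "template") -> Specimen:
    """Wrap the undeformed template as a Specimen (identity deformation)."""
    landmarks = template.landmarks.with_coords(
        template.landmarks.coords, specimen_id=specimen_id
    )
    landmarks.group = group
    return Specimen(
        specimen_id=specimen_id,
        group=group,
        mesh=template.mesh.copy(),
        landmarks=landmarks,
        occipital_semis=template.occipital_semis.copy(),
        template=template,
        deformation=None,
    )


def _random_rigid(rng: np.random.Generator, max_angle: float = np.pi,
                  translation_scale: float = 100.0) -> SimilarityTransform:
    # uniform random rotation via QR of a Gaussian matrix
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-translation_scale, translation_scale, size=3)
    return SimilarityTransform(rotation=Q, translation=t, scale=1.0)


def fragment_specimen(
    specimen: Specimen,
    cutting_plane: tuple[np.ndarray, np.ndarray] | None = None,
    rigid_jitter_sd: float = 0.0,
    seed: int = 0,
    exclusion_band_mm: float = 2.0,
) -> FragmentPair:
    """Split a specimen into two rigidly displaced fragments.

    The cutting plane (default: a coronal plane separating the anterior
    16-landmark and posterior 12-landmark sets) partitions landmarks and
    mesh faces, discarding everything within ``exclusion_band_mm`` of the
    cut so the fragments have no conjoining points. Each fragment then
    receives an independent random rigid motion, recorded as ground truth;
    ``rigid_jitter_sd`` adds Gaussian landmark noise (mm) on top.
    """
    if cutting_plane is None:
        origin = np.array([-8.0, 0.0, 0.0])
        normal = np.array([1.0, 0.0, 0.0])
    else:
        origin, normal = (np.asarray(v, dtype=float) for v in cutting_plane)
        normal = normal / np.linalg.norm(normal)

    lm = specimen.landmarks
    d = (lm.coords - origin) @ normal
    a_idx = [i for i in range(len(lm)) if d[i] > exclusion_band_mm]
    b_idx = [i for i in range(len(lm)) if d[i] < -exclusion_band_mm]
    if len(a_idx) < 4 or len(b_idx) < 4:
        raise ValueError("degenerate split: each fragment needs >= 4 landmarks")

    names_a = [lm.landmark_names[i] for i in a_idx]
    names_b = [lm.landmark_names[i] for i in b_idx]

    rng = np.random.default_rng(seed)
    T_a = _random_rigid(rng)
    T_b = _random_rigid(rng)

    def make_frag(names, T, suffix):
        cfg = lm.subset(names, specimen_id=f"{lm.specimen_id}_{suffix}")
        coords = T.apply(cfg.coords)
        if rigid_jitter_sd > 0:
            coords = coords + rng.normal(0.0, rigid_jitter_sd, size=coords.shape)
        cfg = cfg.with_coords(coords)
        cfg.pairing = _sub_pairing(lm.pairing, names)
        return cfg

    frag_a = make_frag(names_a, T_a, "FF")
    frag_b = make_frag(names_b, T_b, "BP")

    def submesh(side: int, T: SimilarityTransform) -> TriMesh:
        tm = specimen.mesh.as_trimesh()
        vd = (tm.vertices - origin) @ normal
        keep = (vd * side > exclusion_band_mm)[tm.faces].all(axis=1)
        sub = tm.submesh([np.nonzero(keep)[0]], append=True)
        return TriMesh(sub.vertices, sub.faces, validate=False).transformed(T)

    mesh_a = submesh(+1, T_a)
    mesh_b = submesh(-1, T_b)

    return FragmentPair(
        frag_a=frag_a,
        frag_b=frag_b,
        mesh_a=mesh_a,
        mesh_b=mesh_b,
        truth_transform_a=T_a,
        truth_transform_b=T_b,
        source_id=specimen.specimen_id,
    )


def _sub_pairing(pairing: PairingTable | None, names: list[str]) -> PairingTable | None:
    if pairing is None:
        return None
    nameset = set(names)
    pairs = tuple(p for p in pairing.pairs if p[0] in nameset and p[1] in nameset)
    # bilateral landmarks whose partner fell on the other fragment become
    # effectively unpairable; they are dropped from the table only if the
    # partner is absent (cannot happen with a sagittal-symmetric cut)
    midline = tuple(m for m in pairing.midline if m in nameset)
    covered = {x for p in pairs for x in p} | set(midline)
    if covered != nameset:
        return None
    return PairingTable(pairs=pairs, midline=midline)


def generate_endocast(
    specimen: Specimen,
    shell_thickness: float = 8.0,
    subdivisions: int = 3,
) -> TriMesh:
    """Inward-offset endocast shell for a specimen.

    For the undeformed template the endocast is the ellipsoid with
    semi-axes (a-t, b-t, c-t) carrying the same radial modulation, so its
    volume is analytically known when the modulation amplitude is zero.
    For deformed specimens the shell is carried through the specimen's own
    TPS deformation, keeping it consistent with the outer surface.
    """
    t = shell_thickness
    template = specimen.template
    a, b, c = template.semi_axes
    if t <= 0:
        raise ValueError("shell thickness must be positive")
    if t >= min(a, b, c):
        raise ValueError(
            f"shell thickness {t} mm would self-intersect (min semi-axis {min(a, b, c)} mm)"
        )
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    directions = np.asarray(ico.vertices)
    inner = _surface_points(
        directions, template.seed, template.bump_amplitude,
        semi_axes=(a - t, b - t, c - t),
    )
    if specimen.deformation is not None:
        inner = tps_warp(specimen.deformation, inner)
    endo = TriMesh(inner, np.asarray(ico.faces), validate=False)
    if not endo.watertight:
        raise ValueError("generated endocast is not watertight")
    return endo


def analytic_endocast_volume_cc(template: CranialTemplate, shell_thickness: float) -> float:
    """Analytic endocast volume (cc) for the unmodulated ellipsoid."""
    a, b, c = template.semi_axes
    t = shell_thickness
    return 4.0 / 3.0 * np.pi * (a - t) * (b - t) * (c - t) / 1000.0


def simulate_characters(
    tree: PhyloTree,
    n_characters: int = 20,
    substitution_rate: float = 0.5,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> CharacterMatrix:
    """Evolve binary characters along a tree with known truth.

    Each branch flips the state with probability 1 - exp(-rate * length);
    missing values ('?') are injected independently at ``missing_rate``.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    if substitution_rate < 0:
        raise ValueError("substitution_rate must be non-negative")
    rng = np.random.default_rng(seed)
    taxa = tree.leaves
    root, postorder = _preorder(tree)
    rows = {t: [] for t in taxa}
    for _ in range(n_characters):
        state = {root: 0}
        for node, parent in postorder:
            if parent is None:
                continue
            length = tree.edge_length(parent, node) or 0.0
            p_flip = 1.0 - np.exp(-substitution_rate * length)
            s = state[parent]
            if rng.random() < p_flip:
                s = 1 - s
            state[node] = s
        for t in taxa:
            rows[t].append(str(state[t]))
    states = []
    for t in taxa:
        row = rows[t]
        mask = rng.random(n_characters) < missing_rate
        states.append([MISSING if m else s for s, m in zip(row, mask)])
    characters = [f"char_{i + 1}" for i in range(n_characters)]
    return CharacterMatrix(
        taxa=list(taxa),
        characters=characters,
        states=states,
        derived_state_map={c: "1" for c in characters},
    )


def _preorder(tree: PhyloTree):
    """Root at an arbitrary internal node; return (root, preorder (node, parent))."""
    internals = [n for n in tree.adj if not isinstance(n, str)]
    root = internals[0] if internals else next(iter(tree.adj))
    order = []
    stack = [(root, None)]
    seen = {root}
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nbr in tree.adj[node]:
            if nbr not in seen:
                seen.add(nbr)
                stack.append((nbr, node))
    return root, order
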