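"""Synthetic neuron trees and rendered stacks with fully known ground truth.

Every pipeline stage is testable without microscope data: the generator
plants a long main dendrite with sharp bends of chosen angle and arclength,
side branches (soma outgrowths, neurite outgrowths, a PVM-like crossing
branch carrying a soma-sized node), Gaussian radius bumps (beads), and a
spherical soma, then optionally renders the tree into a noisy voxel stack
(tube/sphere rasterization, Gaussian PSF, Poisson photon noise).

Bend corners are placed exactly at their planted arclengths, with the
out-of-plane turn direction randomized so tests exercise genuine 3D
geometry rather than planar special cases.  Cohort generators emulate
aged-worm populations at the distribution level: bend counts Poisson in
the dendrite length, outgrowth counts Poisson, outgrowth lengths
log-normal — and a coupling knob places a fraction of outgrowths within a
fixed distance of a planted bend, which is exactly the signal the
association test must detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d

from .spatial_stats import EventPositions
from .swc_io import NeuronTree, SwcNode
from .soma_volume import ImageStack

__all__ = [
    "NeuronSpec",
    "CohortSpec",
    "GroundTruth",
    "make_neuron",
    "render_stack",
    "make_cohort",
    "sample_cohort_positions",
    "shift_to_positive",
    "match_events",
]


@dataclass(frozen=True)
class NeuronSpec:
    """Planted geometry of one synthetic neuron.

    Arclengths are µm along the main branch from the root end.  ``bend_list``
    holds (arclength, interior angle in degrees); ``branch_list`` holds
    (attachment arclength, branch length, label) with label one of
    ``somaoutgrowth``/``neuriteoutgrowth``/``pvm``; ``bead_list`` holds
    (arclength, amplitude µm, width µm) Gaussian radius bumps.
    """

    main_length: float = 120.0
    node_spacing: float = 0.2
    bend_list: tuple = ()
    branch_list: tuple = ()
    bead_list: tuple = ()
    soma_radius: float | None = None
    baseline_radius: float = 0.4
    radius_noise_sd: float = 0.0
    coordinate_noise_sd: float = 0.0
    rng_seed: int | None = None


@dataclass
class GroundTruth:
    """Exact planted features, for matching against pipeline output."""

    main_length: float
    node_spacing: float
    bends: list = field(default_factory=list)     # (arclength, angle°)
    beads: list = field(default_factory=list)     # arclength
    branches: list = field(default_factory=list)  # (label, attach_s, length)
    soma_radius: float | None = None


@dataclass(frozen=True)
class CohortSpec:
    """Distributional description of a synthetic neuron population.

    Defaults describe an aged wild-type PLM-like cohort: ~300 µm dendrites,
    bend counts Poisson with density 0.04 µm⁻¹ (about 12 bends per neuron),
    bend angles uniform in 90°-150°, bends at least 6.5 µm apart, outgrowth
    counts Poisson with mean 3, outgrowth lengths log-normal around 4 µm.
    ``coupling_prob`` places each outgrowth within ``coupling_distance`` of
    a random bend instead of uniformly — the association signal.
    """

    n_neurons: int = 19
    main_length: float = 300.0
    bend_density: float = 0.04
    bend_angle_range: tuple[float, float] = (90.0, 150.0)
    min_bend_separation: float = 6.5
    outgrowth_rate: float = 3.0
    outgrowth_log_length: tuple[float, float] = (1.4, 0.5)  # log-normal µ, σ
    coupling_prob: float = 0.0
    coupling_distance: float = 0.5
    node_spacing: float = 0.2
    coordinate_noise_sd: float = 0.05
    soma_radius: float | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.coupling_prob <= 1:
            raise ValueError("coupling_prob must be in [0, 1]")


def _rotate(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis``."""
    th = np.radians(angle_deg)
    return (
        v * np.cos(th)
        + np.cross(axis, v) * np.sin(th)
        + axis * np.dot(axis, v) * (1 - np.cos(th))
    )


def _perpendicular(d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random unit vector perpendicular to ``d``."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, d)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    phi = rng.uniform(0, 2 * np.pi)
    return np.cos(phi) * e1 + np.sin(phi) * e2


def make_neuron(spec: NeuronSpec) -> tuple[NeuronTree, GroundTruth]:
    """Realize a :class:`NeuronSpec` as a validated tree plus its ground truth.

    Deterministic under ``spec.rng_seed``.  Raises on infeasible specs
    (bends closer than the node spacing, features beyond the main length,
    side branches long enough to displace the main branch).
    """
    rng = np.random.default_rng(spec.rng_seed)
    bends = sorted(spec.bend_list)
    svals = [s for s, _ in bends]
    if any(s <= 0 or s >= spec.main_length for s in svals):
        raise ValueError("bend arclengths must lie inside (0, main_length)")
    if any(b - a < spec.node_spacing for a, b in zip(svals, svals[1:])):
        raise ValueError("bends closer than the node spacing are infeasible")
    for s, length, label in spec.branch_list:
        if not 0 <= s < spec.main_length:
            raise ValueError("branch attachment beyond the main branch")
        if label != "somaoutgrowth" and s + length >= spec.main_length:
            raise ValueError(
                "side branch would outreach the main branch endpoint"
            )
    for s, _, _ in spec.bead_list:
        if not 0 < s < spec.main_length:
            raise ValueError("bead arclength beyond the main branch")

    nodes: list[SwcNode] = []
    next_id = 1

    def add(pos, radius, parent, code=3):
        nonlocal next_id
        nodes.append(
            SwcNode(
                id=next_id,
                structure_code=code,
                x=float(pos[0]),
                y=float(pos[1]),
                z=float(pos[2]),
                radius=float(radius),
                parent_id=parent,
            )
        )
        next_id += 1
        return next_id - 1

    # ---- soma (optional): center node is the root, plus a shell ----------
    soma_shell: list[int] = []
    if spec.soma_radius is not None:
        R = spec.soma_radius
        root_id = add(np.zeros(3), R, -1, code=1)
        # shell nodes inscribed in the soma sphere (offset + radius = R), so
        # the rendered union of node spheres is exactly the soma sphere
        for off in ([0, R / 10, 0], [0, -R / 10, 0], [0, 0, R / 10],
                    [0, 0, -R / 10]):
            soma_shell.append(add(np.array(off, float), 0.9 * R, root_id, code=1))
        main_parent = root_id
    else:
        root_id = None
        main_parent = -1

    # ---- main branch: straight segments between exact corner nodes -------
    breakpoints = [0.0] + svals + [spec.main_length]
    pos = np.zeros(3)
    d = np.array([1.0, 0.0, 0.0])
    main_ids: list[int] = []
    main_s: list[float] = []

    first = add(pos, spec.baseline_radius, main_parent)
    if main_parent == -1:
        root_id = first
    main_ids.append(first)
    main_s.append(0.0)
    for seg_i in range(len(breakpoints) - 1):
        a, b = breakpoints[seg_i], breakpoints[seg_i + 1]
        n_steps = max(1, round((b - a) / spec.node_spacing))
        sub = (b - a) / n_steps
        for k in range(n_steps):
            pos = pos + d * sub
            main_ids.append(add(pos, spec.baseline_radius, main_ids[-1]))
            main_s.append(a + (k + 1) * sub)
        if seg_i < len(bends):
            _, angle = bends[seg_i]
            axis = _perpendicular(d, rng)
            d = _rotate(d, axis, 180.0 - angle)
            d /= np.linalg.norm(d)

    main_s_arr = np.array(main_s)

    # ---- radius profile: baseline + bead bumps + noise -------------------
    radii = np.full(len(main_ids), spec.baseline_radius)
    for s0, amp, width in spec.bead_list:
        radii += amp * np.exp(-0.5 * ((main_s_arr - s0) / width) ** 2)
    if spec.radius_noise_sd > 0:
        radii += rng.normal(0, spec.radius_noise_sd, size=len(radii))
    radii = np.maximum(radii, 0.05)
    for idx, nid in enumerate(main_ids):
        nodes[nid - 1] = replace(nodes[nid - 1], radius=float(radii[idx]))

    # ---- side branches ----------------------------------------------------
    node_pos = {n.id: n.position for n in nodes}
    main_dirs = np.gradient(np.array([node_pos[i] for i in main_ids]), axis=0)
    branch_chains: list[list[int]] = []
    for s_attach, length, label in spec.branch_list:
        if label == "somaoutgrowth":
            if not soma_shell:
                raise ValueError("somaoutgrowth planted without a soma")
            attach = soma_shell[0] if len(spec.branch_list) == 1 else (
                soma_shell[hash((s_attach, length)) % len(soma_shell)]
            )
            base_dir = node_pos[attach] - np.zeros(3)
            base_dir = base_dir / np.linalg.norm(base_dir)
        else:
            idx = int(np.argmin(np.abs(main_s_arr - s_attach)))
            attach = main_ids[idx]
            md = main_dirs[idx] / np.linalg.norm(main_dirs[idx])
            base_dir = _perpendicular(md, rng)
        n_steps = max(1, round(length / spec.node_spacing))
        sub = length / n_steps
        parent = attach
        p = node_pos[attach]
        chain: list[int] = []
        for k in range(n_steps):
            p = p + base_dir * sub
            r = spec.baseline_radius
            if label == "pvm" and k == n_steps - 1:
                r = 3.0  # the swept-up PVM soma
            parent = add(p, r, parent)
            chain.append(parent)
        branch_chains.append((attach, chain))

    if spec.coordinate_noise_sd > 0:
        # Smooth (correlated) displacement along each chain: tracing error
        # wanders slowly, it is not white per-node jitter, which at fine node
        # spacing would spuriously inflate every measured arclength.  Branch
        # chains inherit their attachment node's displacement so the tree
        # stays geometrically continuous at attachments.
        corr_nodes = max(2.0, 1.0 / spec.node_spacing)

        def smooth_noise(n):
            white = rng.normal(size=(n, 3))
            sm = gaussian_filter1d(white, corr_nodes, axis=0, mode="nearest")
            std = sm.std()
            return sm * (spec.coordinate_noise_sd / std) if std > 0 else sm

        disp: dict[int, np.ndarray] = {}
        sm = smooth_noise(len(main_ids))
        for k, nid in enumerate(main_ids):
            disp[nid] = sm[k]
        for attach, chain in branch_chains:
            sm = smooth_noise(len(chain))
            sm -= sm[0]  # anchored at the attachment
            base = disp.get(attach, np.zeros(3))
            for k, nid in enumerate(chain):
                disp[nid] = base + sm[k]
        for nid, d in disp.items():
            n = nodes[nid - 1]
            nodes[nid - 1] = replace(
                n, x=n.x + d[0], y=n.y + d[1], z=n.z + d[2]
            )
    tree = NeuronTree(nodes)

    gt = GroundTruth(
        main_length=spec.main_length,
        node_spacing=spec.node_spacing,
        bends=list(bends),
        beads=[s for s, _, _ in spec.bead_list],
        branches=[
            (label, 0.0 if label == "somaoutgrowth" else s, length)
            for s, length, label in spec.branch_list
        ],
        soma_radius=spec.soma_radius,
    )
    return tree, gt


def shift_to_positive(tree: NeuronTree, margin_um: float = 2.0) -> NeuronTree:
    """Translate the tree so every node sits at least ``margin_um`` from the
    coordinate origin on each axis (rendering needs positive coordinates)."""
    pts = np.array([tree.nodes[i].position for i in sorted(tree.nodes)])
    radii = np.array([tree.nodes[i].radius for i in sorted(tree.nodes)])
    shift = margin_um + radii.max() - pts.min(axis=0)
    moved = [
        replace(n, x=n.x + shift[0], y=n.y + shift[1], z=n.z + shift[2])
        for n in (tree.nodes[i] for i in sorted(tree.nodes))
    ]
    return NeuronTree(moved)


def render_stack(
    tree: NeuronTree,
    voxel_dims: tuple[float, float, float] = (0.223, 0.223, 0.300),
    psf_sigma: tuple[float, float, float] = (0.7, 0.7, 0.52),
    photon_scale: float | None = 100.0,
    rng_seed: int | None = None,
    margin_um: float = 2.0,
    background: float = 0.1,
    max_shape: tuple[int, int, int] = (256, 1024, 1024),
) -> ImageStack:
    """Rasterize a tree into a voxel stack with PSF blur and Poisson noise.

    Nodes and the segments between them are stamped as spheres of the local
    radius (unit intensity) over a uniform ``background`` (autofluorescence
    plus detector offset), the result is blurred with an anisotropic
    Gaussian PSF (sigma in voxels, (x, y, z) order) and, unless
    ``photon_scale`` is None, Poisson photon noise at that expected count
    per unit intensity is applied.  Deterministic under ``rng_seed``.
    """
    dx, dy, dz = voxel_dims
    ids = sorted(tree.nodes)
    pts = np.array([tree.nodes[i].position for i in ids])
    radii = np.array([tree.nodes[i].radius for i in ids])
    if (pts - radii[:, None]).min() < -1e-9:
        raise ValueError("tree has negative extents; shift_to_positive first")
    hi = pts + radii[:, None] + margin_um
    shape = (
        int(np.ceil(hi[:, 2].max() / dz)) + 1,
        int(np.ceil(hi[:, 1].max() / dy)) + 1,
        int(np.ceil(hi[:, 0].max() / dx)) + 1,
    )
    if any(s > m for s, m in zip(shape, max_shape)):
        raise ValueError(f"tree requires stack shape {shape} > bound {max_shape}")
    img = np.zeros(shape)

    step = min(voxel_dims) / 2.0

    def stamp(center, radius):
        x, y, z = center
        zlo = max(0, int((z - radius) / dz))
        zhi = min(shape[0] - 1, int(np.ceil((z + radius) / dz)))
        ylo = max(0, int((y - radius) / dy))
        yhi = min(shape[1] - 1, int(np.ceil((y + radius) / dy)))
        xlo = max(0, int((x - radius) / dx))
        xhi = min(shape[2] - 1, int(np.ceil((x + radius) / dx)))
        zz, yy, xx = np.meshgrid(
            np.arange(zlo, zhi + 1) * dz,
            np.arange(ylo, yhi + 1) * dy,
            np.arange(xlo, xhi + 1) * dx,
            indexing="ij",
        )
        inside = (zz - z) ** 2 + (yy - y) ** 2 + (xx - x) ** 2 <= radius**2
        np.maximum(
            img[zlo : zhi + 1, ylo : yhi + 1, xlo : xhi + 1],
            inside.astype(float),
            out=img[zlo : zhi + 1, ylo : yhi + 1, xlo : xhi + 1],
        )

    pos_of = {i: tree.nodes[i].position for i in ids}
    for i in ids:
        n = tree.nodes[i]
        stamp(n.position, n.radius)
        if n.parent_id != -1:
            p = pos_of[n.parent_id]
            pr = tree.nodes[n.parent_id].radius
            seg = n.position - p
            seg_len = float(np.linalg.norm(seg))
            if seg_len > step:
                n_sub = int(seg_len / step)
                for k in range(1, n_sub + 1):
                    t = k / (n_sub + 1)
                    stamp(p + t * seg, pr + t * (n.radius - pr))

    if max(psf_sigma) > 0:
        sx, sy, sz = psf_sigma
        img = ndimage.gaussian_filter(img, sigma=(sz, sy, sx), mode="reflect")
    if background > 0:
        img = img + background
    if photon_scale is not None and np.isfinite(photon_scale):
        rng = np.random.default_rng(rng_seed)
        img = rng.poisson(img * photon_scale).astype(float) / photon_scale
    return ImageStack(voxels=img, voxel_dims=voxel_dims)


def sample_cohort_positions(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> list[EventPositions]:
    """Sample per-neuron bend/outgrowth positions only (no tree geometry).

    This is the event layer of :func:`make_cohort`: bends are a hard-core
    point process (Poisson count, minimum separation by rejection),
    outgrowths are uniform or, with ``coupling_prob``, planted within
    ``coupling_distance`` of a random bend.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    cohort = []
    for j in range(spec.n_neurons):
        L = spec.main_length
        n_bends = rng.poisson(spec.bend_density * L)
        bends: list[float] = []
        attempts = 0
        while len(bends) < n_bends and attempts < 10_000:
            s = rng.uniform(2.0, L - 2.0)
            if all(abs(s - b) >= spec.min_bend_separation for b in bends):
                bends.append(s)
            attempts += 1
        bends.sort()
        n_out = rng.poisson(spec.outgrowth_rate)
        outs = []
        for _ in range(n_out):
            if bends and rng.uniform() < spec.coupling_prob:
                b = bends[rng.integers(len(bends))]
                s = np.clip(
                    b + rng.uniform(-spec.coupling_distance,
                                    spec.coupling_distance),
                    0.0,
                    L,
                )
            else:
                s = rng.uniform(0, L)
            outs.append(float(s))
        cohort.append(
            EventPositions(
                neuron_id=f"sim{j:03d}",
                bend_positions=np.array(bends),
                outgrowth_positions=np.array(outs),
                main_length=L,
            )
        )
    return cohort


def make_cohort(
    spec: CohortSpec,
) -> list[tuple[NeuronTree, GroundTruth]]:
    """Draw i.i.d. neurons from a :class:`CohortSpec` as full trees.

    Event positions come from :func:`sample_cohort_positions`; each bend
    becomes a planted corner with an angle drawn from
    ``bend_angle_range`` and each outgrowth a neurite-outgrowth branch of
    log-normal length, attached at its sampled arclength.
    """
    rng = np.random.default_rng(spec.rng_seed)
    positions = sample_cohort_positions(spec, rng)
    out = []
    for j, ep in enumerate(positions):
        angles = rng.uniform(*spec.bend_angle_range, size=ep.bend_positions.size)
        mu, sd = spec.outgrowth_log_length
        lengths = rng.lognormal(mu, sd, size=ep.outgrowth_positions.size)
        branch_list = []
        for s, length in zip(ep.outgrowth_positions, lengths):
            # keep side branches short of the distal tip so the planted main
            # path stays the longest root-to-endpoint path
            s = float(min(s, spec.main_length - 1.5))
            length = float(
                np.clip(length, spec.node_spacing, spec.main_length - s - 1.0)
            )
            branch_list.append((s, length, "neuriteoutgrowth"))
        nspec = NeuronSpec(
            main_length=spec.main_length,
            node_spacing=spec.node_spacing,
            bend_list=tuple(zip(ep.bend_positions.tolist(), angles.tolist())),
            branch_list=tuple(branch_list),
            soma_radius=spec.soma_radius,
            coordinate_noise_sd=spec.coordinate_noise_sd,
            rng_seed=int(rng.integers(2**31)),
        )
        out.append(make_neuron(nspec))
    return out


def match_events(
    true_positions, detected_positions, tol: float = 1.0
) -> tuple[int, int, int]:
    """Greedy 1D matching of detected to planted events within ``tol`` µm.

    Returns ``(matched, missed, false_positive)`` counts; every planted
    event matches at most one detection and vice versa, closest pairs
    first.
    """
    t = list(enumerate(np.asarray(true_positions, dtype=float)))
    d = list(enumerate(np.asarray(detected_positions, dtype=float)))
    pairs = sorted(
        ((abs(tv - dv), ti, di) for ti, tv in t for di, dv in d),
        key=lambda x: x[0],
    )
    used_t: set[int] = set()
    used_d: set[int] = set()
    matched = 0
    for dist, ti, di in pairs:
        if dist > tol:
            break
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        matched += 1
    return matched, len(t) - matched, len(d) - matched
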