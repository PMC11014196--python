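"""Quasi-static complex-conductivity field solver.

Solves ∇·(γ∇V) = 0 on structured tensor-product grids, where
γ(f) = σ + j·2πf·ε0·εr is the local complex admittivity.  The same
discretisation serves all three scales of the study:

* periodic micro/meso units are homogenised by imposing a potential drop
  across one axis and reading off the volume-averaged current (effective
  admittivity);
* the macro tetrapolar problem injects unit current at the drive
  electrode, extracts it at ground, and reports the transfer impedance
  Z = (V1 − V2)/I.

Discretisation: node-centred finite volumes on a (possibly nonuniform)
tensor grid with per-cell admittivity.  Each grid edge carries the
conductance of the four cell quadrants around it, which makes stacked
slabs behave exactly as series resistors (the harmonic-mean closed form)
when interfaces coincide with grid planes.  The 8 nm cell membrane is
never meshed: it enters as an equivalent thin layer of thickness h whose
admittivity is scaled by h/t_m so the per-area admittance γ_m/t_m is
preserved.

Coordinates: z is depth, positive downward from the electrode plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ElectrodeLayout, MacroDomain, MesoUnit, MicroUnit

__all__ = [
    "TransferImpedance",
    "homogenise_cells",
    "effective_admittivity",
    "tetrapolar_impedance",
    "analytic_halfspace_impedance",
    "SolverError",
]

UM = 1e-6  # µm → m
MM = 1e-3  # mm → m

#: Grid-density presets.  Values are cells per characteristic feature;
#: "coarse" is for smoke tests and batch screening, "default" carries the
#: documented convergence level, "fine" is for convergence checks.
RESOLUTIONS = {
    "coarse": {"interior": 3, "gap": 1, "meso_n": 16, "macro_h0": 0.25, "macro_ratio": 1.6},
    "default": {"interior": 5, "gap": 2, "meso_n": 28, "macro_h0": 0.125, "macro_ratio": 1.4},
    "fine": {"interior": 8, "gap": 3, "meso_n": 40, "macro_h0": 0.0625, "macro_ratio": 1.3},
}


class SolverError(RuntimeError):
    """A field solve failed (singular system or non-convergence)."""


@dataclass(frozen=True)
class TransferImpedance:
    """Tetrapolar transfer impedance at one frequency."""

    f: float  # Hz
    Z: complex  # Ω

    def __post_init__(self) -> None:
        if not np.isfinite(self.Z):
            raise SolverError(f"non-finite transfer impedance at {self.f} Hz")


# ----------------------------------------------------------------------
# Core finite-volume machinery
# ----------------------------------------------------------------------

def _edge_conductances(x, y, z, gamma):
    """Per-edge conductances along each axis.

    ``gamma`` has shape (ncx, ncy, ncz) = (len(x)-1, len(y)-1, len(z)-1).
    Each edge collects γ·(cross-section quadrant)/length from the up-to-
    four cells sharing it.
    """
    dx, dy, dz = np.diff(x), np.diff(y), np.diff(z)

    def quarter(a, ax1, ax2):
        """Spread cell contributions onto the nodes of two axes."""
        shape = list(a.shape)
        shape[ax1] += 1
        shape[ax2] += 1
        out = np.zeros(shape, dtype=a.dtype)
        sl = [slice(None)] * 3
        for o1 in (0, 1):
            for o2 in (0, 1):
                s = list(sl)
                s[ax1] = slice(o1, a.shape[ax1] + o1)
                s[ax2] = slice(o2, a.shape[ax2] + o2)
                out[tuple(s)] += a
        return out

    ax_area = gamma * (dy[None, :, None] * dz[None, None, :]) / 4.0
    gx = quarter(ax_area, 1, 2) / dx[:, None, None]
    ay_area = gamma * (dx[:, None, None] * dz[None, None, :]) / 4.0
    gy = quarter(ay_area, 0, 2) / dy[None, :, None]
    az_area = gamma * (dx[:, None, None] * dy[None, :, None]) / 4.0
    gz = quarter(az_area, 0, 1) / dz[None, None, :]
    return gx, gy, gz


def _assemble(x, y, z, gamma):
    """Sparse nodal admittance matrix of the finite-volume network."""
    nx, ny, nz = len(x), len(y), len(z)
    n = nx * ny * nz
    gx, gy, gz = _edge_conductances(x, y, z, gamma)

    idx = np.arange(n).reshape(nx, ny, nz)
    rows, cols, vals = [], [], []
    for g, sh in ((gx, (1, 0, 0)), (gy, (0, 1, 0)), (gz, (0, 0, 1))):
        a = idx[: nx - sh[0], : ny - sh[1], : nz - sh[2]].ravel()
        b = idx[sh[0]:, sh[1]:, sh[2]:].ravel()
        gv = g.ravel()
        rows += [a, b, a, b]
        cols += [a, b, b, a]
        vals += [gv, gv, -gv, -gv]
    L = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return L, idx


def _solve(L, b, fixed_nodes, fixed_values):
    """Direct solve with Dirichlet rows substituted in place."""
    L = L.tolil()
    b = b.astype(complex).copy()
    for node, val in zip(fixed_nodes, fixed_values):
        L.rows[node] = [node]
        L.data[node] = [1.0]
        b[node] = val
    try:
        v = spla.spsolve(L.tocsc(), b)
    except RuntimeError as exc:  # pragma: no cover - singular systems
        raise SolverError(str(exc)) from exc
    if not np.all(np.isfinite(v)):
        raise SolverError("field solve produced non-finite potentials")
    return v


# ----------------------------------------------------------------------
# Homogenisation (micro and meso scales)
# ----------------------------------------------------------------------

def homogenise_cells(x, y, z, gamma, axis: int = 2) -> complex:
    """Effective admittivity of a cell-wise composite along one axis.

    A unit average field is imposed along ``axis`` via Dirichlet planes
    on the two end faces (zero-flux laterally, the periodic-symmetry
    condition for mirror-symmetric units), and the effective admittivity
    is the volume-averaged current density divided by the average field.
    """
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    gamma = np.asarray(gamma, dtype=complex)
    L, idx = _assemble(x, y, z, gamma)
    axes = (x, y, z)
    length = axes[axis][-1] - axes[axis][0]
    area = np.prod([a[-1] - a[0] for i, a in enumerate(axes) if i != axis])

    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = 0
    sl_hi[axis] = -1
    lo = idx[tuple(sl_lo)].ravel()
    hi = idx[tuple(sl_hi)].ravel()
    vlo, vhi = 1.0, 0.0

    b = np.zeros(L.shape[0], dtype=complex)
    v = _solve(
        L,
        b,
        np.concatenate([lo, hi]),
        np.concatenate([np.full(lo.size, vlo), np.full(hi.size, vhi)]),
    )

    # Current entering through the high-potential face.
    gx, gy, gz = _edge_conductances(x, y, z, gamma)
    g_axis = (gx, gy, gz)[axis]
    sl_g = [slice(None)] * 3
    sl_g[axis] = 0
    sl_next = [slice(None)] * 3
    sl_next[axis] = 1
    nshape = (len(x), len(y), len(z))
    vgrid = v.reshape(nshape)
    current = np.sum(
        g_axis[tuple(sl_g)] * (vgrid[tuple(sl_lo)] - vgrid[tuple(sl_next)])
    )
    return complex(current * length / (area * (vlo - vhi)))


def _segment(a: float, b: float, n: int) -> np.ndarray:
    return np.linspace(a, b, max(int(n), 1) + 1)


def _micro_axes_and_gamma(unit: MicroUnit, f: float, resolution: str, include_membrane: bool):
    res = RESOLUTIONS[resolution]
    mem = unit.materials["membrane"]
    t_m = mem.thickness if mem.thickness is not None else 8e-9

    def axis_points(cell_um: float, gap_um: float, h_um: float):
        """Breakpoints (m) along one axis and the region labels per segment."""
        e = gap_um / 2.0
        pts = [0.0]
        labels = []  # one per segment: 'ecs' | 'mem' | 'cyt'

        def add(to, label, ncells):
            seg = _segment(pts[-1], to, ncells)[1:]
            pts.extend(seg.tolist())
            labels.extend([label] * len(seg))

        if e > 0:
            add(e, "ecs", res["gap"])
        add(e + h_um, "mem", 1)
        add(e + cell_um - h_um, "cyt", res["interior"])
        add(e + cell_um, "mem", 1)
        if e > 0:
            add(cell_um + gap_um, "ecs", res["gap"])
        return np.asarray(pts) * UM, labels

    # Equivalent membrane layer: thin against the cell but thick enough
    # to mesh; admittivity rescaled below so γ/h matches γ_m/t_m.
    h_um = 0.04 * min(unit.xcell, unit.ycell, unit.zcell)

    axes, labels = [], []
    for cell, gap in (
        (unit.xcell, unit.dECS),
        (unit.ycell, unit.dECS),
        (unit.zcell, unit.dECS),
    ):
        p, lab = axis_points(cell, gap, h_um)
        axes.append(p)
        labels.append(lab)

    g_cyt = unit.materials.gamma("cytoplasm", f)
    g_ecs = unit.materials.gamma("extracellular_fluid", f)
    g_mem = mem.gamma(f) * (h_um * UM / t_m) if include_membrane else g_cyt

    lx, ly, lz = labels
    nx, ny, nz = len(lx), len(ly), len(lz)
    gamma = np.empty((nx, ny, nz), dtype=complex)
    ax_l = np.array(lx)[:, None, None]
    ay_l = np.array(ly)[None, :, None]
    az_l = np.array(lz)[None, None, :]
    is_ecs = (ax_l == "ecs") | (ay_l == "ecs") | (az_l == "ecs")
    is_mem = ~is_ecs & ((ax_l == "mem") | (ay_l == "mem") | (az_l == "mem"))
    gamma[...] = g_cyt
    gamma[is_mem] = g_mem
    gamma[is_ecs] = g_ecs
    return axes, gamma


def _meso_axes_and_gamma(unit: MesoUnit, f: float, shell_gamma: complex, resolution: str):
    res = RESOLUTIONS[resolution]
    n = res["meso_n"]
    L = unit.edge_length * UM
    ax = np.linspace(0.0, L, n + 1)
    c = L / 2.0
    mid = (ax[:-1] + ax[1:]) / 2.0
    X, Y, Z = np.meshgrid(mid - c, mid - c, mid - c, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    r_shell = unit.dfollicle / 2.0 * UM
    r_core = unit.core_diameter / 2.0 * UM
    gamma = np.full(
        (n, n, n), unit.materials.gamma("connective_tissue", f), dtype=complex
    )
    gamma[r < r_shell] = shell_gamma
    gamma[r < r_core] = unit.materials.gamma("colloid", f)
    return (ax, ax, ax), gamma


def effective_admittivity(
    unit: MicroUnit | MesoUnit,
    f: float,
    shell_gamma: complex | None = None,
    resolution: str = "default",
    include_membrane: bool = True,
) -> complex:
    """Homogenised complex admittivity of a periodic unit at frequency f.

    Micro units need no extra input; meso (follicle) units require
    ``shell_gamma``, the micro-scale effective admittivity assigned to
    the epithelial shell.  The unit is homogenised along the depth axis
    and treated as isotropic.
    """
    if f <= 0:
        raise ValueError("frequency must be > 0")
    if isinstance(unit, MicroUnit):
        axes, gamma = _micro_axes_and_gamma(unit, f, resolution, include_membrane)
    elif isinstance(unit, MesoUnit):
        if shell_gamma is None:
            raise ValueError("meso homogenisation requires shell_gamma")
        axes, gamma = _meso_axes_and_gamma(unit, f, shell_gamma, resolution)
    else:
        raise TypeError(f"cannot homogenise {type(unit).__name__}")
    return homogenise_cells(*axes, gamma, axis=2)


# ----------------------------------------------------------------------
# Macro tetrapolar problem
# ----------------------------------------------------------------------

def _graded(start: float, stop: float, h0: float, ratio: float) -> np.ndarray:
    """Points from start towards stop with geometrically growing steps."""
    pts = [start]
    h = h0
    direction = 1.0 if stop > start else -1.0
    while (stop - pts[-1]) * direction > 1e-12:
        nxt = pts[-1] + direction * h
        if (stop - nxt) * direction < 0.25 * h:
            nxt = stop
        pts.append(nxt)
        h *= ratio
    return np.asarray(pts)


def _macro_axes(domain: MacroDomain, resolution: str):
    res = RESOLUTIONS[resolution]
    h0 = res["macro_h0"]  # mm, fine step under the electrodes
    ratio = res["macro_ratio"]
    lay = domain.layout
    r = lay.radius
    ex = sorted(p[0] for p in lay.positions.values())
    ey = sorted(p[1] for p in lay.positions.values())

    def lateral(core_lo, core_hi, half_width, must=()):
        core = np.arange(core_lo, core_hi + h0 / 2, h0)
        left = _graded(core_lo, -half_width, h0, ratio)[1:]
        right = _graded(core_hi, half_width, h0, ratio)[1:]
        pts = np.concatenate([left[::-1], core, right])
        pts = np.unique(np.concatenate([pts, np.asarray(must, dtype=float)]))
        return pts

    must_x = must_y = ()
    if domain.dpara is not None:
        must_x = must_y = (-domain.dpara / 2.0, domain.dpara / 2.0)
    x = lateral(ex[0] - 2 * r, ex[-1] + 2 * r, domain.width / 2.0, must_x)
    y = lateral(ey[0] - 2 * r, ey[-1] + 2 * r, domain.width / 2.0, must_y)

    z0 = 0.0
    zpts = [0.0]
    if domain.dfascia is not None:
        zpts += list(_segment(0.0, domain.dfascia, 2)[1:])
        z0 = domain.dfascia
    deep = _graded(z0, domain.depth, max(h0, 0.1), ratio)[1:]
    zpts += deep.tolist()
    z = np.asarray(zpts)
    if domain.dpara is not None:
        z = np.unique(np.concatenate([z, [z0 + domain.dpara]]))
    return x * MM, y * MM, z * MM


def _macro_gamma(domain: MacroDomain, f: float, x, y, z):
    cx = (x[:-1] + x[1:]) / 2.0
    cy = (y[:-1] + y[1:]) / 2.0
    cz = (z[:-1] + z[1:]) / 2.0
    bulk = complex(domain.bulk_gamma(f))
    gamma = np.full((cx.size, cy.size, cz.size), bulk, dtype=complex)
    z0 = 0.0
    if domain.dfascia is not None:
        z0 = domain.dfascia * MM
        gamma[:, :, cz < z0] = domain.materials.gamma("fascia", f)
    if domain.gland == "parathyroid":
        bg = domain.materials.gamma("background", f)
        half = domain.dpara / 2.0 * MM
        inside = (
            (np.abs(cx)[:, None, None] < half)
            & (np.abs(cy)[None, :, None] < half)
            & (cz[None, None, :] >= z0)
            & (cz[None, None, :] < z0 + domain.dpara * MM)
        )
        gamma[:, :, cz >= z0] = bg
        gamma[inside] = bulk
    return gamma


def _electrode_nodes(layout: ElectrodeLayout, x, y, idx, model: str):
    """Surface-node sets (z = 0 plane) for each electrode."""
    nodes = {}
    X, Y = np.meshgrid(x, y, indexing="ij")
    for name, (px, py) in layout.positions.items():
        px, py = px * MM, py * MM
        if model == "point":
            i = int(np.argmin(np.abs(x - px)))
            j = int(np.argmin(np.abs(y - py)))
            nodes[name] = np.array([idx[i, j, 0]])
        elif model == "disc":
            mask = (X - px) ** 2 + (Y - py) ** 2 <= (layout.radius * MM) ** 2
            sel = idx[:, :, 0][mask]
            if sel.size == 0:  # grid coarser than the disc
                i = int(np.argmin(np.abs(x - px)))
                j = int(np.argmin(np.abs(y - py)))
                sel = np.array([idx[i, j, 0]])
            nodes[name] = sel
        else:
            raise ValueError(f"unknown electrode model {model!r}")
    return nodes


def tetrapolar_impedance(
    domain: MacroDomain,
    f: float,
    resolution: str = "default",
    electrode_model: str = "disc",
) -> TransferImpedance:
    """Transfer impedance of the macro domain at one frequency.

    Unit current is injected at the drive electrode I1 and extracted at
    ground V0; disc electrodes are equipotential node groups, point
    electrodes single nodes.  Z = (V(V1) − V(V2)) / I.
    """
    x, y, z = _macro_axes(domain, resolution)
    gamma = _macro_gamma(domain, f, x, y, z)
    L, idx = _assemble(x, y, z, gamma)
    n = L.shape[0]
    nodes = _electrode_nodes(domain.layout, x, y, idx, electrode_model)

    # Merge each electrode's nodes into an equipotential supernode.
    reduce_map = np.arange(n)
    for sel in nodes.values():
        reduce_map[sel] = sel[0]
    _, compressed = np.unique(reduce_map, return_inverse=True)
    m = compressed.max() + 1
    P = sp.csr_matrix((np.ones(n), (np.arange(n), compressed)), shape=(n, m))
    Lr = (P.T @ L @ P).tocsr()

    b = np.zeros(m, dtype=complex)
    b[compressed[nodes["I1"][0]]] += 1.0
    b[compressed[nodes["V0"][0]]] -= 1.0

    # Ground a far-field corner node to pin the Neumann nullspace.
    ground = compressed[idx[0, 0, -1]]
    vr = _solve(Lr, b, np.array([ground]), np.array([0.0]))
    zval = vr[compressed[nodes["V1"][0]]] - vr[compressed[nodes["V2"][0]]]
    return TransferImpedance(f=f, Z=complex(zval))


def analytic_halfspace_impedance(layout: ElectrodeLayout, sigma: float) -> float:
    """Four-point transfer impedance of a homogeneous half-space (Ω).

    Point-electrode potential theory: each point source on the surface of
    a half-space of conductivity σ produces V = I/(2πσr), so

        Z = (1/2πσ) · (1/r(I1,V1) − 1/r(I1,V2) − 1/r(V0,V1) + 1/r(V0,V2)).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    pairs = [("I1", "V1", +1), ("I1", "V2", -1), ("V0", "V1", -1), ("V0", "V2", +1)]
    total = 0.0
    for a, b, sign in pairs:
        rab = layout.separation(a, b) * MM
        if rab == 0:
            raise ValueError(f"electrodes {a} and {b} coincide")
        total += sign / rab
    return total / (2.0 * np.pi * sigma)
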