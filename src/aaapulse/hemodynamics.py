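"""Frequency-domain pulse-wave solver for a rooted arterial transmission-line network.

The systemic arterial tree is modelled as rooted chains of uniform, linear,
lossy transmission lines (one per artery). Each line is characterised by its
geometry (length ``l``, inner radius ``r``, wall thickness ``h``) and wall
stiffness (Young's modulus ``E``); blood contributes viscous and inertial
properties. Terminal branches are closed by 3-parameter Windkessel loads
(proximal resistance R1, distal resistance R2, compliance C) that lump the
arterioles and capillaries.

The solve is harmonic-by-harmonic: the aortic inflow is decomposed into
Fourier harmonics of the heart period, the input impedance of the whole tree
is assembled leaf-to-root (daughters combine in parallel at bifurcations),
root pressure follows as ``P = Z_in * Q``, and pressure is propagated
root-to-leaf through each line via forward/backward travelling waves with the
distal reflection coefficient ``Gamma = (Z_L - Zc)/(Z_L + Zc)``. The mean
(DC) component is solved on the Poiseuille-resistance skeleton. The periodic
steady state is obtained by construction.

An abdominal aortic aneurysm (AAA) is introduced by replacing the infrarenal
abdominal aorta segment (``TL_31`` in the packaged 55-artery anatomy) with a
chain of short sub-segments whose radii follow a cosine-bump dilation profile
and whose wall stiffness is scaled by a factor ``K_E``.

Units are SI throughout; pressures are reported in mmHg at the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy.interpolate import CubicSpline
from scipy.special import jv

__all__ = [
    "MMHG_PA",
    "BloodProperties",
    "ArterialSegmentSpec",
    "TerminalLoad",
    "ArterialTree",
    "AneurysmSpec",
    "SimulationSettings",
    "Waveform",
    "PeriodicSignal",
    "aaa_radius_profile",
    "vsi_from_geometry",
    "solve_asl",
    "insert_aneurysm",
    "womersley_f10",
    "longitudinal_impedance",
    "wall_compliance_per_length",
    "characteristic_impedance",
    "propagation_constant",
    "windkessel_impedance",
    "input_impedance",
    "aortic_inflow",
    "simulate_pressures",
    "solve_tree",
    "load_anatomy",
    "nominal_tree",
]

MMHG_PA = 133.322  # Pa per mmHg

#: Maximum attainable relative luminal-area increase of the aneurysm bump.
ASL_MAX = 5.25
#: Normalising constant of the volumetric severity index: the largest
#: attainable relative volume excess V_AAA/V0 - 1 (at l_aaa = 1, a_sl = 5.25).
VSI_NORM = ASL_MAX / 2.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BloodProperties:
    """Bulk blood properties: density (kg/m^3) and dynamic viscosity (Pa s)."""

    density: float = 1050.0
    viscosity: float = 4.0e-3

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("blood density and viscosity must be positive")


@dataclass
class ArterialSegmentSpec:
    """One uniform transmission line: geometry, stiffness and topology."""

    id: int
    name: str
    length: float
    radius: float
    thickness: float
    youngs_modulus: float
    parent_id: int | None
    terminal: bool = False

    def __post_init__(self) -> None:
        for attr in ("length", "radius", "thickness", "youngs_modulus"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"segment {self.id}: {attr} must be positive")
        if self.thickness >= self.radius:
            raise ValueError(f"segment {self.id}: wall thickness must be < radius")

    @property
    def area(self) -> float:
        return math.pi * self.radius**2


@dataclass
class TerminalLoad:
    """3-parameter Windkessel: R_T split into R1/R2 plus a compliance."""

    r_total: float
    compliance: float
    proximal_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.r_total <= 0 or self.compliance <= 0:
            raise ValueError("Windkessel resistance and compliance must be positive")
        if not 0.0 < self.proximal_fraction < 1.0:
            raise ValueError("proximal_fraction must lie in (0, 1)")

    @property
    def r1(self) -> float:
        return self.proximal_fraction * self.r_total

    @property
    def r2(self) -> float:
        return (1.0 - self.proximal_fraction) * self.r_total


class ConfigurationError(ValueError):
    """Raised for structurally invalid trees or missing anatomy entries."""


@dataclass
class ArterialTree:
    """A rooted, acyclic network of arterial segments with terminal loads.

    ``sites`` maps measurement-site names to ``(segment id, axial fraction)``
    pairs, the fraction measured from the segment inlet in [0, 1].
    """

    segments: dict[int, ArterialSegmentSpec]
    loads: dict[int, TerminalLoad]
    sites: dict[str, tuple[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        roots = [s.id for s in self.segments.values() if s.parent_id is None]
        if len(roots) != 1:
            raise ConfigurationError(f"tree must have exactly one root, found {roots}")
        children: dict[int, list[int]] = {}
        for seg in self.segments.values():
            if seg.parent_id is not None:
                if seg.parent_id not in self.segments:
                    raise ConfigurationError(
                        f"segment {seg.id} references unknown parent {seg.parent_id}"
                    )
                children.setdefault(seg.parent_id, []).append(seg.id)
        # connectivity / acyclicity via traversal from the root
        seen: set[int] = set()
        stack = [roots[0]]
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise ConfigurationError("cycle detected in arterial tree")
            seen.add(sid)
            stack.extend(children.get(sid, []))
        if seen != set(self.segments):
            raise ConfigurationError("arterial tree is not connected")
        for seg in self.segments.values():
            has_children = bool(children.get(seg.id))
            if seg.terminal and has_children:
                raise ConfigurationError(f"terminal segment {seg.id} has children")
            if not seg.terminal and not has_children:
                raise ConfigurationError(f"leaf segment {seg.id} not marked terminal")
            if seg.terminal and seg.id not in self.loads:
                raise ConfigurationError(f"terminal segment {seg.id} has no load")
        for name, (sid, frac) in self.sites.items():
            if sid not in self.segments:
                raise ConfigurationError(f"site {name!r} references unknown segment {sid}")
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"site {name!r} fraction outside [0, 1]")

    @property
    def root_id(self) -> int:
        return next(s.id for s in self.segments.values() if s.parent_id is None)

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {sid: [] for sid in self.segments}
        for seg in self.segments.values():
            if seg.parent_id is not None:
                out[seg.parent_id].append(seg.id)
        return out

    def copy(self) -> "ArterialTree":
        return ArterialTree(
            segments={k: replace(v) for k, v in self.segments.items()},
            loads={k: replace(v) for k, v in self.loads.items()},
            sites=dict(self.sites),
        )

    def path_length_to_site(self, site: str) -> float:
        """Length (m) along the tree from the root inlet to the named site."""
        sid, frac = self.sites[site]
        total = frac * self.segments[sid].length
        seg = self.segments[sid]
        while seg.parent_id is not None:
            seg = self.segments[seg.parent_id]
            total += seg.length
        return total

    # -- serialisation -----------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "ArterialTree":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ArterialTree":
        segments: dict[int, ArterialSegmentSpec] = {}
        loads: dict[int, TerminalLoad] = {}
        for row in doc["segments"]:
            seg = ArterialSegmentSpec(
                id=int(row["id"]),
                name=str(row["name"]),
                length=float(row["length"]),
                radius=float(row["radius"]),
                thickness=float(row["thickness"]),
                youngs_modulus=float(row["youngs_modulus"]),
                parent_id=None if row.get("parent") in (None, 0, "root") else int(row["parent"]),
                terminal=bool(row.get("terminal", False)),
            )
            segments[seg.id] = seg
            if seg.terminal:
                loads[seg.id] = TerminalLoad(
                    r_total=float(row["r_total"]),
                    compliance=float(row["compliance"]),
                    proximal_fraction=float(row.get("proximal_fraction", 0.2)),
                )
        sites = {
            str(k): (int(v[0]), float(v[1])) for k, v in doc.get("sites", {}).items()
        }
        return cls(segments=segments, loads=loads, sites=sites)

    def to_dict(self) -> dict:
        rows = []
        for seg in sorted(self.segments.values(), key=lambda s: s.id):
            row = {
                "id": seg.id,
                "name": seg.name,
                "parent": seg.parent_id,
                "length": seg.length,
                "radius": seg.radius,
                "thickness": seg.thickness,
                "youngs_modulus": seg.youngs_modulus,
                "terminal": seg.terminal,
            }
            if seg.terminal:
                load = self.loads[seg.id]
                row.update(
                    r_total=load.r_total,
                    compliance=load.compliance,
                    proximal_fraction=load.proximal_fraction,
                )
            rows.append(row)
        return {"segments": rows, "sites": {k: list(v) for k, v in self.sites.items()}}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_anatomy(path) -> ArterialTree:
    """Load an anatomy table (YAML segment table) into an :class:`ArterialTree`."""
    return ArterialTree.from_yaml(path)


_NOMINAL_CACHE: dict | None = None


def nominal_tree() -> ArterialTree:
    """The packaged 55-artery nominal anatomy (Avolio-type table).

    Returns a fresh copy each call; callers may mutate freely.
    """
    global _NOMINAL_CACHE
    if _NOMINAL_CACHE is None:
        from importlib.resources import files

        with files("aaapulse.data").joinpath("anatomy55.yaml").open() as fh:
            _NOMINAL_CACHE = yaml.safe_load(fh)
    return ArterialTree.from_dict(_NOMINAL_CACHE)


# ---------------------------------------------------------------------------
# aneurysm geometry
# ---------------------------------------------------------------------------


def aaa_radius_profile(x, r0: float, a_sl: float):
    """Radius of the aneurysmal dilation at normalised position ``x``.

    The luminal cross-sectional area scales as
    ``1 + (a_sl/2) * (1 - cos(2 pi (x + 1/2)))`` for ``x`` in [-1/2, 1/2],
    so the radius is ``r0`` at both ends and peaks at the centre ``x = 0``
    with value ``r0 * sqrt(1 + a_sl)``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < -0.5) or np.any(x > 0.5):
        raise ValueError("normalised position x must lie in [-0.5, 0.5]")
    if not 0.0 <= a_sl <= ASL_MAX:
        raise ValueError(f"a_sl must lie in [0, {ASL_MAX}]")
    area_factor = 1.0 + (a_sl / 2.0) * (1.0 - np.cos(2.0 * np.pi * (x + 0.5)))
    out = r0 * np.sqrt(area_factor)
    return out if out.ndim else float(out)


def vsi_from_geometry(l_aaa: float, a_sl: float) -> float:
    """Volumetric severity index (%) from bump extent and area parameter.

    The relative volume excess of the cosine bump integrates exactly to
    ``l_aaa * a_sl / 2``; the index normalises this by its maximum 2.625.
    """
    if not 0.0 < l_aaa <= 1.0:
        raise ValueError("l_aaa must lie in (0, 1]")
    if not 0.0 <= a_sl <= ASL_MAX:
        raise ValueError(f"a_sl must lie in [0, {ASL_MAX}]")
    return 100.0 * (l_aaa * a_sl / 2.0) / VSI_NORM


class FeasibilityError(ValueError):
    """Raised when a (vsi, l_aaa) pair would require a_sl > its maximum."""


def solve_asl(vsi: float, l_aaa: float) -> float:
    """Invert the severity index for the area parameter at fixed bump extent."""
    if not 0.0 <= vsi <= 100.0:
        raise ValueError("vsi must lie in [0, 100]")
    if not 0.0 < l_aaa <= 1.0:
        raise ValueError("l_aaa must lie in (0, 1]")
    if l_aaa < vsi / 100.0 - 1e-12:
        raise FeasibilityError(
            f"vsi={vsi}% infeasible at l_aaa={l_aaa}: would need a_sl > {ASL_MAX}"
        )
    return ASL_MAX * (vsi / 100.0) / l_aaa


@dataclass
class AneurysmSpec:
    """Parameterisation of the infrarenal dilation.

    ``l_aaa`` is the bump extent as a fraction of the host segment length,
    ``a_sl`` the relative peak area increase, ``k_e`` the wall-stiffness
    scaling of the dilated wall, and ``vsi`` the volumetric severity index
    in percent. The triplet (vsi, l_aaa, a_sl) must be mutually consistent.
    """

    l_aaa: float
    a_sl: float
    k_e: float
    vsi: float
    n_subsegments: int = 16

    def __post_init__(self) -> None:
        if not 0.0 < self.l_aaa <= 1.0:
            raise ValueError("l_aaa must lie in (0, 1]")
        if not 0.0 <= self.a_sl <= ASL_MAX + 1e-9:
            raise ValueError(f"a_sl must lie in [0, {ASL_MAX}]")
        if self.k_e <= 0:
            raise ValueError("k_e must be positive")
        if self.n_subsegments < 8:
            raise ValueError("n_subsegments must be >= 8")
        expected = vsi_from_geometry(self.l_aaa, self.a_sl)
        if abs(expected - self.vsi) > 1e-6:
            raise ValueError(
                f"inconsistent AneurysmSpec: vsi={self.vsi} but geometry implies {expected}"
            )

    @classmethod
    def from_vsi(
        cls, vsi: float, l_aaa: float, k_e: float, n_subsegments: int = 16
    ) -> "AneurysmSpec":
        a_sl = solve_asl(vsi, l_aaa)
        return cls(l_aaa=l_aaa, a_sl=a_sl, k_e=k_e, vsi=vsi, n_subsegments=n_subsegments)

    @property
    def max_diameter_increase_pct(self) -> float:
        """Percent increase of the maximum luminal diameter over the healthy one."""
        return 100.0 * (math.sqrt(1.0 + self.a_sl) - 1.0)


def insert_aneurysm(
    tree: ArterialTree, spec: AneurysmSpec, host_site: str = "TL_31"
) -> ArterialTree:
    """Return a new tree with the aneurysm carved into the host segment.

    The host segment is replaced by a chain: an (optional) healthy proximal
    stub, ``n_subsegments`` uniform cells whose radii sample the dilation
    profile at cell midpoints (wall stiffness scaled by ``k_e``), and an
    (optional) healthy distal stub. The bump is centred and total length is
    preserved; sites on the host segment are remapped by arc length.
    """
    if host_site not in tree.sites:
        raise ConfigurationError(f"tree has no site {host_site!r}")
    host_id = tree.sites[host_site][0]
    host = tree.segments[host_id]
    children = tree.children_map()[host_id]

    total_l = host.length
    bump_l = spec.l_aaa * total_l
    stub_l = 0.5 * (total_l - bump_l)
    n = spec.n_subsegments
    cell_l = bump_l / n

    new_id = max(tree.segments) + 1
    segments = {k: replace(v) for k, v in tree.segments.items()}
    del segments[host_id]

    chain: list[ArterialSegmentSpec] = []
    bounds: list[float] = []  # inlet arc-length of each chain element
    pos = 0.0
    parent = host.parent_id

    def _append(name: str, length: float, radius: float, emod: float) -> None:
        nonlocal new_id, parent, pos
        seg = ArterialSegmentSpec(
            id=new_id,
            name=name,
            length=length,
            radius=radius,
            thickness=host.thickness,
            youngs_modulus=emod,
            parent_id=parent,
            terminal=False,
        )
        chain.append(seg)
        bounds.append(pos)
        parent = new_id
        new_id += 1
        pos += length

    if stub_l > 1e-12:
        _append(f"{host.name}_prox", stub_l, host.radius, host.youngs_modulus)
    mid_x = -0.5 + (np.arange(n) + 0.5) / n
    radii = aaa_radius_profile(mid_x, host.radius, spec.a_sl)
    for i in range(n):
        _append(
            f"{host.name}_aaa{i:02d}",
            cell_l,
            float(radii[i]),
            host.youngs_modulus * spec.k_e,
        )
    if stub_l > 1e-12:
        _append(f"{host.name}_dist", stub_l, host.radius, host.youngs_modulus)

    chain[-1].terminal = host.terminal
    for seg in chain:
        segments[seg.id] = seg
    for cid in children:
        segments[cid].parent_id = chain[-1].id

    loads = {k: replace(v) for k, v in tree.loads.items()}
    if host.terminal:
        loads[chain[-1].id] = loads.pop(host_id)

    # remap sites on the host segment by arc length
    sites: dict[str, tuple[int, float]] = {}
    edges = np.array(bounds + [total_l])
    for name, (sid, frac) in tree.sites.items():
        if sid != host_id:
            sites[name] = (sid, frac)
            continue
        s = min(frac * total_l, total_l - 1e-12)
        k = int(np.searchsorted(edges, s, side="right") - 1)
        seg = chain[k]
        sites[name] = (seg.id, (s - edges[k]) / seg.length)

    return ArterialTree(segments=segments, loads=loads, sites=sites)


# ---------------------------------------------------------------------------
# transmission-line constitutive relations (Womersley theory, thin wall)
# ---------------------------------------------------------------------------

_F10_SPLINE: CubicSpline | None = None
_F10_LOG_LO, _F10_LOG_HI = math.log(1e-4), math.log(600.0)


def _f10_exact(alpha: np.ndarray) -> np.ndarray:
    """F10 via Bessel functions of complex argument (exact path)."""
    alpha = np.asarray(alpha, dtype=float)
    out = np.empty(alpha.shape, dtype=complex)
    small = alpha < 1e-4
    big = alpha > 600.0
    mid = ~(small | big)
    if np.any(mid):
        z = alpha[mid] * np.exp(3j * np.pi / 4.0)
        out[mid] = 2.0 * jv(1, z) / (z * jv(0, z))
    if np.any(small):
        a2 = alpha[small] ** 2
        # series of 2 J1(z)/(z J0(z)) with z^2 = -i alpha^2
        out[small] = 1.0 - 1j * a2 / 8.0 - a2**2 / 48.0
    if np.any(big):
        # J1/J0 -> i in the upper half plane, so F10 -> 2i/z
        z = alpha[big] * np.exp(3j * np.pi / 4.0)
        out[big] = 2j / z
    return out


def womersley_f10(alpha, exact: bool = False):
    """Womersley function ``F10(alpha) = 2 J1(z) / (z J0(z))``, ``z = i^{3/2} alpha``.

    The default path evaluates a cubic-spline tabulation of the exact Bessel
    expression (relative error < 1e-8 over the physiologic range), which is
    far cheaper inside cohort-scale solves; ``exact=True`` forces the direct
    Bessel evaluation.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0):
        raise ValueError("alpha must be nonnegative")
    if exact:
        out = _f10_exact(alpha)
        return out if out.ndim else complex(out)
    global _F10_SPLINE
    if _F10_SPLINE is None:
        grid = np.exp(np.linspace(_F10_LOG_LO, _F10_LOG_HI, 6000))
        _F10_SPLINE = CubicSpline(np.log(grid), _f10_exact(grid))
    out = np.empty(alpha.shape, dtype=complex)
    inside = (alpha >= math.exp(_F10_LOG_LO)) & (alpha <= math.exp(_F10_LOG_HI))
    if np.any(inside):
        out[inside] = _F10_SPLINE(np.log(alpha[inside]))
    if np.any(~inside):
        out[~inside] = _f10_exact(alpha[~inside])
    return out if out.ndim else complex(out)


def _longitudinal_impedance_rw(radius, blood: BloodProperties, omega):
    """Per-length longitudinal impedance from radius and blood, vectorised."""
    radius = np.asarray(radius, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be nonnegative")
    area = np.pi * radius**2
    alpha = radius * np.sqrt(omega * blood.density / blood.viscosity)
    poiseuille = 8.0 * blood.viscosity / (np.pi * radius**4)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = 1j * omega * blood.density / area / (1.0 - womersley_f10(alpha))
    # omega == 0 reduces exactly to the Poiseuille resistance per length
    z = np.where(omega == 0.0, poiseuille + 0j, z)
    return z


def longitudinal_impedance(seg: ArterialSegmentSpec, blood: BloodProperties, omega):
    """Womersley per-length longitudinal impedance Z' (Pa s / m^4) of a line."""
    out = _longitudinal_impedance_rw(seg.radius, blood, omega)
    return out if np.ndim(out) else complex(out)


def wall_compliance_per_length(seg: ArterialSegmentSpec) -> float:
    """Thin-wall elastic-tube compliance per unit length C' = 3 pi r^3 / (2 E h)."""
    return 3.0 * math.pi * seg.radius**3 / (2.0 * seg.youngs_modulus * seg.thickness)


def characteristic_impedance(seg: ArterialSegmentSpec, blood: BloodProperties, omega):
    """Zc = sqrt(Z' / (j omega C')) — requires omega > 0 (DC handled separately)."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("characteristic impedance requires omega > 0")
    zl = longitudinal_impedance(seg, blood, omega)
    cp = wall_compliance_per_length(seg)
    out = np.sqrt(zl / (1j * omega * cp))
    return out if np.ndim(out) else complex(out)


def propagation_constant(seg: ArterialSegmentSpec, blood: BloodProperties, omega):
    """gamma = sqrt(Z' * j omega C') — requires omega > 0."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("propagation constant requires omega > 0")
    zl = longitudinal_impedance(seg, blood, omega)
    cp = wall_compliance_per_length(seg)
    out = np.sqrt(zl * 1j * omega * cp)
    return out if np.ndim(out) else complex(out)


def windkessel_impedance(load: TerminalLoad, omega):
    """Z(omega) = R1 + R2 / (1 + j omega R2 C)."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be nonnegative")
    out = load.r1 + load.r2 / (1.0 + 1j * omega * load.r2 * load.compliance)
    return out if np.ndim(out) else complex(out)


def input_impedance(seg: ArterialSegmentSpec, z_load, blood: BloodProperties, omega):
    """Input impedance of a loaded line: Zc (Z_L + Zc tanh(g l)) / (Zc + Z_L tanh(g l)).

    ``z_load=np.inf`` gives the open-circuit limit ``Zc / tanh(g l)``.
    """
    zc = characteristic_impedance(seg, blood, omega)
    gl = propagation_constant(seg, blood, omega) * seg.length
    t = np.tanh(gl)
    if np.isscalar(z_load) and np.isinf(z_load):
        out = zc / t
    else:
        out = zc * (z_load + zc * t) / (zc + np.asarray(z_load) * t)
    return out if np.ndim(out) else complex(out)


# ---------------------------------------------------------------------------
# waveforms and inflow
# ---------------------------------------------------------------------------


@dataclass
class SimulationSettings:
    """Record geometry and harmonic resolution of the periodic solve."""

    fs: float = 128.0
    duration: float = 2.0
    n_harmonics: int = 40
    settling: str = "periodic"

    def __post_init__(self) -> None:
        if self.n_samples != round(self.fs * self.duration):
            raise ValueError("fs * duration must be an integer number of samples")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def harmonic_count(self, f0: float) -> int:
        """Harmonics actually used: capped strictly below the Nyquist of fs."""
        nyq_cap = int(math.floor((self.fs / 2.0 - 1e-9) / f0))
        return max(1, min(self.n_harmonics, nyq_cap))


@dataclass
class PeriodicSignal:
    """One-sided Fourier representation of a T-periodic signal.

    ``x(t) = mean + sum_k 2 Re(coeffs[k-1] exp(j k w0 t))`` with
    ``w0 = 2 pi / period``.
    """

    mean: float
    coeffs: np.ndarray  # complex, harmonics 1..K
    period: float

    @property
    def omega(self) -> np.ndarray:
        k = np.arange(1, len(self.coeffs) + 1)
        return 2.0 * np.pi * k / self.period

    def sample(self, t: np.ndarray) -> np.ndarray:
        ph = np.exp(1j * np.outer(t, self.omega))
        return self.mean + 2.0 * np.real(ph @ self.coeffs)


@dataclass
class Waveform:
    """A fixed-rate record at one measurement site.

    ``kind`` is one of ``pressure`` (mmHg), ``flow`` (m^3/s) or ``pvr``
    (arbitrary volume-like units). When the record was synthesised from a
    periodic steady state, ``periodic`` carries the exact harmonic form.
    """

    site: str
    kind: str
    samples: np.ndarray
    fs: float
    periodic: PeriodicSignal | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


def aortic_inflow(
    hr: float, sv: float, settings: SimulationSettings | None = None
, systole_scale: float = 0.3) -> Waveform:
    """Half-sine systolic ejection into the ascending aorta.

    Ejection lasts ``T_sys = systole_scale * sqrt(60 / hr)`` seconds with zero
    diastolic flow; the per-beat integral equals the stroke volume exactly and
    the peak flow is ``sv * pi / (2 T_sys)``.
    """
    if not 60.0 <= hr <= 90.0:
        raise ValueError("heart rate must lie in [60, 90] bpm")
    if sv <= 0:
        raise ValueError("stroke volume must be positive")
    settings = settings or SimulationSettings()
    period = 60.0 / hr
    t_sys = systole_scale * math.sqrt(60.0 / hr)
    if t_sys >= period:
        raise ValueError("systolic duration exceeds the beat period")
    qp = sv * math.pi / (2.0 * t_sys)

    f0 = 1.0 / period
    n_harm = settings.harmonic_count(f0)
    # Fourier coefficients of one beat sampled densely (aliasing error ~1e-8)
    nfine = 8192
    tt = np.arange(nfine) * (period / nfine)
    q = np.where(tt <= t_sys, qp * np.sin(np.pi * np.minimum(tt, t_sys) / t_sys), 0.0)
    spec = np.fft.rfft(q) / nfine
    periodic = PeriodicSignal(mean=sv / period, coeffs=spec[1 : n_harm + 1], period=period)
    # exact time-domain samples (no Gibbs ringing in diastole)
    t = np.arange(settings.n_samples) / settings.fs
    tb = np.mod(t, period)
    samples = np.where(tb <= t_sys, qp * np.sin(np.pi * np.minimum(tb, t_sys) / t_sys), 0.0)
    return Waveform(site="ascending_aorta", kind="flow", samples=samples, fs=settings.fs, periodic=periodic)


# ---------------------------------------------------------------------------
# compiled tree + periodic solve
# ---------------------------------------------------------------------------


class NumericalFailure(RuntimeError):
    """Raised when the harmonic solve produces an unphysical result."""


class CompiledTree:
    """Array view of an :class:`ArterialTree` organised by depth levels.

    Building the arrays once per realisation lets the leaf-to-root impedance
    recursion and the root-to-leaf propagation run as a handful of vectorised
    operations per tree level.
    """

    def __init__(self, tree: ArterialTree, blood: BloodProperties | None = None):
        self.tree = tree
        self.blood = blood or BloodProperties()
        ids = sorted(tree.segments)
        self.index = {sid: i for i, sid in enumerate(ids)}
        n = len(ids)
        segs = [tree.segments[sid] for sid in ids]
        self.length = np.array([s.length for s in segs])
        self.radius = np.array([s.radius for s in segs])
        self.thickness = np.array([s.thickness for s in segs])
        self.emod = np.array([s.youngs_modulus for s in segs])
        self.terminal = np.array([s.terminal for s in segs])
        self.parent = np.array(
            [self.index[s.parent_id] if s.parent_id is not None else -1 for s in segs]
        )
        self.r1 = np.zeros(n)
        self.r2 = np.zeros(n)
        self.cw = np.full(n, np.nan)
        for sid, load in tree.loads.items():
            i = self.index[sid]
            self.r1[i], self.r2[i], self.cw[i] = load.r1, load.r2, load.compliance
        depth = np.zeros(n, dtype=int)
        children: list[list[int]] = [[] for _ in range(n)]
        root = -1
        for i in range(n):
            if self.parent[i] >= 0:
                children[self.parent[i]].append(i)
            else:
                root = i
        stack = [(root, 0)]
        while stack:
            i, d = stack.pop()
            depth[i] = d
            for c in children[i]:
                stack.append((c, d + 1))
        self.root = root
        self.depth = depth
        self.children = children
        self.levels = [np.flatnonzero(depth == d) for d in range(depth.max() + 1)]
        self.sites = {k: (self.index[sid], frac) for k, (sid, frac) in tree.sites.items()}

    # -- harmonic solve ----------------------------------------------------
    def solve(self, inflow: PeriodicSignal) -> "TreeSolution":
        blood = self.blood
        omega = inflow.omega  # (K,)
        r = self.radius[:, None]
        area = np.pi * r**2
        zl = _longitudinal_impedance_rw(r, blood, omega[None, :])
        cp = (3.0 * np.pi * self.radius**3 / (2.0 * self.emod * self.thickness))[:, None]
        jwc = 1j * omega[None, :] * cp
        gamma = np.sqrt(zl * jwc)
        zc = np.sqrt(zl / jwc)
        gl = gamma * self.length[:, None]
        tanh_gl = np.tanh(gl)
        exp_ml = np.exp(-gl)

        n, k = zl.shape
        z_load = np.zeros((n, k), dtype=complex)
        term = self.terminal
        z_load[term] = (
            self.r1[term, None]
            + self.r2[term, None]
            / (1.0 + 1j * omega[None, :] * self.r2[term, None] * self.cw[term, None])
        )
        acc = np.zeros((n, k), dtype=complex)
        z_in = np.empty((n, k), dtype=complex)
        for level in reversed(self.levels):
            nt = level[~term[level]]
            if nt.size:
                z_load[nt] = 1.0 / acc[nt]
            zc_l, t_l, zl_l = zc[level], tanh_gl[level], z_load[level]
            z_in[level] = zc_l * (zl_l + zc_l * t_l) / (zc_l + zl_l * t_l)
            par = self.parent[level]
            has_par = par >= 0
            if np.any(has_par):
                np.add.at(acc, par[has_par], 1.0 / z_in[level][has_par])

        gamma_r = (z_load - zc) / (z_load + zc)
        denom = 1.0 + gamma_r * exp_ml**2

        q_root = inflow.coeffs
        p_in = np.zeros((n, k), dtype=complex)
        p_in[self.root] = z_in[self.root] * q_root
        p_out = np.empty((n, k), dtype=complex)
        for level in self.levels:
            p_out[level] = (
                p_in[level] * exp_ml[level] * (1.0 + gamma_r[level]) / denom[level]
            )
            for i in level:
                for c in self.children[i]:
                    p_in[c] = p_out[i]

        # DC (mean) component on the resistive skeleton
        r_seg = 8.0 * blood.viscosity * self.length / (np.pi * self.radius**4)
        r_in = np.empty(n)
        acc_dc = np.zeros(n)
        for level in reversed(self.levels):
            rl = np.where(term[level], self.r1[level] + self.r2[level], 1.0 / np.where(acc_dc[level] == 0, np.inf, acc_dc[level]))
            r_in[level] = r_seg[level] + rl
            par = self.parent[level]
            has_par = par >= 0
            if np.any(has_par):
                np.add.at(acc_dc, par[has_par], 1.0 / r_in[level][has_par])
        q_mean = np.zeros(n)
        p_in_dc = np.zeros(n)
        q_mean[self.root] = inflow.mean
        p_in_dc[self.root] = inflow.mean * r_in[self.root]
        p_out_dc = np.empty(n)
        for level in self.levels:
            p_out_dc[level] = p_in_dc[level] - q_mean[level] * r_seg[level]
            for i in level:
                for c in self.children[i]:
                    p_in_dc[c] = p_out_dc[i]
                    q_mean[c] = p_out_dc[i] / r_in[c]

        if np.any(np.real(z_in[self.root]) < 0):
            raise NumericalFailure("negative real part in root input impedance")

        return TreeSolution(
            compiled=self,
            inflow=inflow,
            omega=omega,
            gamma=gamma,
            zc=zc,
            z_in=z_in,
            z_load=z_load,
            gamma_r=gamma_r,
            p_in=p_in,
            p_out=p_out,
            q_mean=q_mean,
            p_in_dc=p_in_dc,
            r_seg_dc=r_seg,
            r_in_dc=r_in,
        )


@dataclass
class TreeSolution:
    """Per-harmonic pressure field of one periodic solve."""

    compiled: CompiledTree
    inflow: PeriodicSignal
    omega: np.ndarray
    gamma: np.ndarray
    zc: np.ndarray
    z_in: np.ndarray
    z_load: np.ndarray
    gamma_r: np.ndarray
    p_in: np.ndarray
    p_out: np.ndarray
    q_mean: np.ndarray
    p_in_dc: np.ndarray
    r_seg_dc: np.ndarray
    r_in_dc: np.ndarray

    def pressure_harmonics_at(self, idx: int, frac: float) -> PeriodicSignal:
        """Pressure (Pa) at axial fraction ``frac`` of compiled segment ``idx``."""
        c = self.compiled
        l = c.length[idx]
        g = self.gamma[idx]
        e2 = np.exp(-2.0 * g * l)
        pf = self.p_in[idx] / (1.0 + self.gamma_r[idx] * e2)
        x = frac * l
        coeffs = pf * (np.exp(-g * x) + self.gamma_r[idx] * e2 * np.exp(g * x))
        mean = self.p_in_dc[idx] - self.q_mean[idx] * self.r_seg_dc[idx] * frac
        return PeriodicSignal(mean=mean, coeffs=coeffs, period=self.inflow.period)

    def flow_harmonics_at(self, idx: int, frac: float) -> PeriodicSignal:
        c = self.compiled
        l = c.length[idx]
        g = self.gamma[idx]
        e2 = np.exp(-2.0 * g * l)
        pf = self.p_in[idx] / (1.0 + self.gamma_r[idx] * e2)
        x = frac * l
        coeffs = pf * (np.exp(-g * x) - self.gamma_r[idx] * e2 * np.exp(g * x)) / self.zc[idx]
        return PeriodicSignal(mean=self.q_mean[idx], coeffs=coeffs, period=self.inflow.period)

    def site_pressure(self, site: str) -> PeriodicSignal:
        idx, frac = self.compiled.sites[site]
        return self.pressure_harmonics_at(idx, frac)

    def site_waveform(self, site: str, settings: SimulationSettings) -> Waveform:
        sig = self.site_pressure(site)
        t = np.arange(settings.n_samples) / settings.fs
        samples = sig.sample(t) / MMHG_PA
        sig_mmhg = PeriodicSignal(sig.mean / MMHG_PA, sig.coeffs / MMHG_PA, sig.period)
        return Waveform(site=site, kind="pressure", samples=samples, fs=settings.fs, periodic=sig_mmhg)


def solve_tree(
    tree: ArterialTree,
    inflow: Waveform,
    blood: BloodProperties | None = None,
) -> TreeSolution:
    """Solve the periodic pressure field of ``tree`` driven by ``inflow``."""
    if inflow.periodic is None:
        raise ValueError(
            "inflow must carry its periodic harmonic representation "
            "(use aortic_inflow or attach a PeriodicSignal)"
        )
    return CompiledTree(tree, blood).solve(inflow.periodic)


def simulate_pressures(
    tree: ArterialTree,
    inflow: Waveform,
    settings: SimulationSettings | None = None,
    sites: Iterable[str] | None = None,
    blood: BloodProperties | None = None,
) -> dict[str, Waveform]:
    """Simulate site pressure waveforms (mmHg) for the named measurement sites."""
    settings = settings or SimulationSettings()
    sol = solve_tree(tree, inflow, blood)
    names = list(sites) if sites is not None else list(tree.sites)
    return {name: sol.site_waveform(name, settings) for name in names}
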