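"""Synthetic torso CT phantoms with exact ground-truth compartment masks.

The phantom emulates a whole-torso CT at the 1.96 x 1.96 x 2.5 mm working
resolution: an elliptical, gently tapering trunk built from concentric
layers (skin, subcutaneous fat ring, abdominal wall muscle, inner organ
tissue), two lung ellipsoids, a vertebral column with enclosed marrow
cavities, a pelvic bone ring whose anterior arc plays the pubic symphysis,
chains of overlapping visceral fat blobs, bowel gas pockets, and a detached
scanner couch bar.  Voxel HU = compartment mean + Gaussian noise.

Everything is placed with >= 2 voxels of clearance between compartments of
different tissue classes (except by-construction contacts such as wall ->
organ), and bone is separated from muscle-valued tissue by a 3-voxel
connective cushion so the "no bone in component" muscle rule behaves as it
does on real anatomy.

What the phantom does NOT model: partial-volume blur at the native
resolution (unless ``supersample`` is used), beam hardening, metal or
motion artifacts, and organ-level HU heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import CTVolume, LabelMask
from .tissue import TissueMaps

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "default_specs"]

# compartment codes
_BG, _SKIN, _SUBCUT, _WALL, _ORGAN = 0, 1, 2, 3, 4
_BONE, _MARROW, _LUNG, _GAS, _BLOB, _CONNECTIVE, _COUCH = 5, 6, 7, 8, 9, 10, 11

_DEFAULT_HU = {
    _BG: -1000.0, _SKIN: 20.0, _SUBCUT: -100.0, _WALL: 50.0, _ORGAN: 50.0,
    _BONE: 400.0, _MARROW: 20.0, _LUNG: -800.0, _GAS: -1000.0,
    _BLOB: -100.0, _CONNECTIVE: 0.0, _COUCH: 60.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and imaging parameters of one synthetic subject.

    Lengths are in working-resolution voxel units; ``torso_semiaxes`` are the
    (x, y) semi-axes at the torso's axial midpoint, shrinking linearly by
    ``taper`` toward both ends.
    """

    name: str = "phantom"
    shape: tuple[int, int, int] = (96, 96, 144)
    spacing: tuple[float, float, float] = (1.96, 1.96, 2.5)
    torso_semiaxes: tuple[float, float] = (35.0, 29.0)
    taper: float = 0.03
    skin_thickness: float = 1.0
    subcut_thickness: float = 6.0
    wall_thickness: float = 6.0
    lung_offset_x: float = 14.0
    lung_center: tuple[float, float] = (50.0, 25.0)   # (y, z)
    lung_semiaxes: tuple[float, float, float] = (6.0, 9.0, 11.0)
    torso_z: tuple[int, int] = (2, 141)
    spine_z: tuple[int, int] = (19, 124)
    pelvis_z: tuple[int, int] = (108, 124)
    n_visceral_blobs: int = 15
    blob_radius_range: tuple[float, float] = (2.6, 3.6)
    n_gas_pockets: int = 3
    gas_radius: float = 2.5
    hu: dict = field(default_factory=lambda: dict(_DEFAULT_HU))
    noise_sigma: float = 3.0
    seed: int = 0
    couch: bool = True
    supersample: bool = False  # generate at 2x grid / half spacing


@dataclass
class PhantomTruth:
    """Painted compartments plus the analytic quantities the pipeline estimates."""

    tissues: TissueMaps            # trunk/bone/muscle/air/fat as painted
    visceral_fat: LabelMask
    subcutaneous_fat: LabelMask
    pubis_z: int                   # cranial edge of the pubic ring
    superior_plane_z: float        # first z plane caudal to both lungs
    lung_base: np.ndarray          # per-column caudal lung z (NaN off-lung)
    voxel_volume_mm3: float

    @property
    def visceral_volume_cm3(self) -> float:
        return self.visceral_fat.count() * self.voxel_volume_mm3 / 1000.0

    @property
    def subcutaneous_volume_cm3(self) -> float:
        return self.subcutaneous_fat.count() * self.voxel_volume_mm3 / 1000.0


def _paint(codes: np.ndarray, where: np.ndarray, code: int, allowed: tuple[int, ...]) -> None:
    if not np.isin(codes[where], allowed).all():
        bad = set(np.unique(codes[where])) - set(allowed)
        raise ValueError(f"overlapping compartment specification: code {code} over {sorted(bad)}")
    codes[where] = code


class _Builder:
    """Paints one phantom; all geometry is expressed in working-voxel units."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.k = 2 if spec.supersample else 1
        nx, ny, nz = spec.shape
        self.shape = (nx * self.k, ny * self.k, nz * self.k)
        self.cx, self.cy = nx / 2.0, ny / 2.0
        # voxel-center coordinates in working units
        self.xw = (np.arange(self.shape[0]) + 0.5) / self.k - 0.5
        self.yw = (np.arange(self.shape[1]) + 0.5) / self.k - 0.5
        self.zw = (np.arange(self.shape[2]) + 0.5) / self.k - 0.5
        z0, z1 = spec.torso_z
        self.zmid = (z0 + z1) / 2.0
        self.zhalf = (z1 - z0) / 2.0
        sc = spec.skin_thickness + spec.subcut_thickness + spec.wall_thickness
        self.cavity_margin = sc
        cav_b = spec.torso_semiaxes[1] - sc
        self.y_spine = self.cy - cav_b + 9.0
        self.rng = np.random.default_rng(spec.seed)

    # --- geometry helpers -------------------------------------------------
    def _scale(self, z: float) -> float:
        return 1.0 - self.spec.taper * abs(z - self.zmid) / self.zhalf

    def _cavity_semi(self, z: float) -> tuple[float, float]:
        s = self._scale(z)
        ax, ay = self.spec.torso_semiaxes
        return s * ax - self.cavity_margin, s * ay - self.cavity_margin

    def _sphere(self, center, r) -> np.ndarray:
        cx, cy, cz = center
        return (
            (self.xw[:, None, None] - cx) ** 2
            + (self.yw[None, :, None] - cy) ** 2
            + (self.zw[None, None, :] - cz) ** 2
        ) <= r * r

    def _allowed_center(self, c, r, gas) -> bool:
        x, y, z = c
        if not (46.0 + r <= z <= 103.0 - r):
            return False
        zworst = z + r if abs(z + r - self.zmid) > abs(z - r - self.zmid) else z - r
        ca, cb = self._cavity_semi(zworst)
        ca, cb = ca - r - 2.0, cb - r - 2.0
        if ca <= 0 or cb <= 0:
            return False
        if ((x - self.cx) / ca) ** 2 + ((y - self.cy) / cb) ** 2 > 1.0:
            return False
        if abs(x - self.cx) <= 8.0 + r and abs(y - self.y_spine) <= 8.0 + r:
            return False  # vertebral column + cushion, expanded
        for gc, gr in gas:
            if np.hypot(np.hypot(x - gc[0], y - gc[1]), z - gc[2]) < r + gr + 2.0:
                return False
        return True

    # --- painting ---------------------------------------------------------
    def build(self) -> tuple[np.ndarray, dict]:
        sp = self.spec
        codes = np.zeros(self.shape, dtype=np.uint8)
        ax, ay = sp.torso_semiaxes
        z0, z1 = sp.torso_z

        # concentric trunk layers from the boundary-distance map
        body = np.zeros(self.shape, dtype=bool)
        inz = (self.zw >= z0) & (self.zw <= z1)
        s = np.array([self._scale(z) for z in self.zw])
        rad = ((self.xw[:, None, None] - self.cx) / (s[None, None, :] * ax)) ** 2 + (
            (self.yw[None, :, None] - self.cy) / (s[None, None, :] * ay)
        ) ** 2
        body = (rad <= 1.0) & inz[None, None, :]
        depth = ndimage.distance_transform_edt(np.pad(body, 1))[1:-1, 1:-1, 1:-1] / self.k
        codes[body] = _ORGAN
        codes[body & (depth <= 1 + sp.subcut_thickness + sp.wall_thickness)] = _WALL
        codes[body & (depth <= 1 + sp.subcut_thickness)] = _SUBCUT
        codes[body & (depth <= sp.skin_thickness)] = _SKIN

        # pelvic interior: connective soft tissue, no muscle around the ring
        pz0, pz1 = sp.pelvis_z
        pelvic = (codes == _ORGAN) & (self.zw[None, None, :] >= pz0 - 2) & (
            self.zw[None, None, :] <= pz1 + 2
        )
        codes[pelvic] = _CONNECTIVE

        # vertebral column: bone box in a 3-voxel connective cushion
        sz0, sz1 = sp.spine_z
        inspine_z = (self.zw >= sz0) & (self.zw <= sz1)
        # cushion extends 3 voxels past the column ends so bone never touches
        # muscle-valued tissue (which would trip the no-bone muscle rule)
        incushion_z = (self.zw >= sz0 - 3) & (self.zw <= sz1 + 3)
        bx = np.abs(self.xw[:, None, None] - self.cx)
        by = np.abs(self.yw[None, :, None] - self.y_spine)
        cushion = (bx <= 6) & (by <= 6) & incushion_z[None, None, :]
        bone_box = (bx <= 3) & (by <= 3) & inspine_z[None, None, :]
        _paint(codes, cushion & ~bone_box, _CONNECTIVE, (_ORGAN, _CONNECTIVE))
        _paint(codes, bone_box, _BONE, (_ORGAN, _CONNECTIVE))
        # enclosed marrow cavities every 9 voxels along the column
        marrow_z = np.zeros(len(self.zw), dtype=bool)
        zc = sz0 + 2.0
        while zc + 4.0 <= sz1 - 2.0:
            marrow_z |= (self.zw >= zc) & (self.zw <= zc + 3.0)
            zc += 9.0
        marrow = (bx <= 1) & (by <= 1) & marrow_z[None, None, :]
        _paint(codes, marrow, _MARROW, (_BONE,))

        # pelvic ring; its anterior arc is the pubic symphysis
        inring_z = (self.zw >= pz0) & (self.zw <= pz1)
        u_out = ((self.xw[:, None, None] - self.cx) / 16.0) ** 2 + (
            (self.yw[None, :, None] - self.cy) / 10.0
        ) ** 2
        u_in = ((self.xw[:, None, None] - self.cx) / 13.0) ** 2 + (
            (self.yw[None, :, None] - self.cy) / 7.0
        ) ** 2
        ring = (u_out <= 1.0) & (u_in > 1.0) & inring_z[None, None, :]
        _paint(codes, ring, _BONE, (_CONNECTIVE, _BONE, _MARROW))
        self.pubis_index = int(np.argwhere(ring.any(axis=(0, 1)))[0, 0])

        # lungs
        ly, lz = sp.lung_center
        la, lb, lc = sp.lung_semiaxes
        for sgn in (+1, -1):
            lung = (
                ((self.xw[:, None, None] - (self.cx + sgn * sp.lung_offset_x)) / la) ** 2
                + ((self.yw[None, :, None] - ly) / lb) ** 2
                + ((self.zw[None, None, :] - lz) / lc) ** 2
            ) <= 1.0
            _paint(codes, lung, _LUNG, (_ORGAN,))

        # bowel gas pockets
        gas: list[tuple[tuple[float, float, float], float]] = []
        tries = 0
        while len(gas) < sp.n_gas_pockets:
            tries += 1
            if tries > 20000:
                raise ValueError("could not place gas pockets; spec region too small")
            c = (
                self.rng.uniform(self.cx - 30, self.cx + 30),
                self.rng.uniform(self.cy - 20, self.cy + 20),
                self.rng.uniform(50.0, 100.0),
            )
            if self._allowed_center(c, sp.gas_radius, gas):
                gas.append((c, sp.gas_radius))
        for c, r in gas:
            _paint(codes, self._sphere(c, r), _GAS, (_ORGAN,))

        # visceral fat: chains of overlapping blobs (contiguous mesenteric masses)
        lo, hi = sp.blob_radius_range
        n_chains = max(1, int(round(sp.n_visceral_blobs / 15)))
        per = np.full(n_chains, sp.n_visceral_blobs // n_chains)
        per[: sp.n_visceral_blobs % n_chains] += 1
        blob_mask = np.zeros(self.shape, dtype=bool)
        for n in per:
            prev = None
            placed = 0
            tries = 0
            while placed < n:
                r = self.rng.uniform(lo, hi)
                if prev is None:
                    c = (
                        self.rng.uniform(self.cx - 30, self.cx + 30),
                        self.rng.uniform(self.cy - 20, self.cy + 20),
                        self.rng.uniform(46.0, 103.0),
                    )
                    tries += 1
                    if tries > 20000:
                        raise ValueError("could not seed a fat chain; spec region too small")
                    if not self._allowed_center(c, r, gas):
                        continue
                else:
                    c = prev
                    for _ in range(60):
                        step = self.rng.normal(size=3)
                        step *= 3.0 / np.linalg.norm(step)
                        cand = tuple(np.asarray(prev) + step)
                        if self._allowed_center(cand, r, gas):
                            c = cand
                            break
                blob_mask |= self._sphere(c, r)
                prev = c
                placed += 1
        _paint(codes, blob_mask, _BLOB, (_ORGAN, _BLOB))

        # detached couch bar
        if sp.couch:
            couch = (
                (self.xw[:, None, None] >= self.cx - 24)
                & (self.xw[:, None, None] <= self.cx + 24)
                & (self.yw[None, :, None] >= 2)
                & (self.yw[None, :, None] <= 5)
                & inz[None, None, :]
            )
            _paint(codes, couch, _COUCH, (_BG,))

        return codes


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Render a phantom volume and its exact ground truth.

    Deterministic for a given spec (including its ``seed``); raises on a
    geometrically impossible (overlapping) specification.
    """
    b = _Builder(spec)
    codes = b.build()
    lut = np.array([spec.hu.get(c, -1000.0) for c in range(12)])
    vox = lut[codes]
    if spec.noise_sigma > 0:
        vox = vox + b.rng.normal(0.0, spec.noise_sigma, size=codes.shape)
    spacing = tuple(s / b.k for s in spec.spacing)
    vol = CTVolume(vox, spacing)

    def mask(*cs):
        return LabelMask(np.isin(codes, cs), spacing)

    lungs = codes == _LUNG
    nz = codes.shape[2]
    lung_base = np.where(
        lungs.any(axis=2),
        np.where(lungs, np.arange(nz)[None, None, :], -1).max(axis=2).astype(float),
        np.nan,
    )
    superior_plane = float(np.nanmax(lung_base)) + 1.0 if lungs.any() else 0.0
    tissues = TissueMaps(
        trunk=mask(_SKIN, _SUBCUT, _WALL, _ORGAN, _BONE, _MARROW, _LUNG, _GAS, _BLOB, _CONNECTIVE),
        bone=mask(_BONE, _MARROW),
        muscle=mask(_WALL, _ORGAN),
        air=mask(_LUNG, _GAS),
        fat=mask(_SUBCUT, _BLOB),
    )
    truth = PhantomTruth(
        tissues=tissues,
        visceral_fat=mask(_BLOB),
        subcutaneous_fat=mask(_SUBCUT),
        pubis_z=b.pubis_index,
        superior_plane_z=superior_plane,
        lung_base=lung_base,
        voxel_volume_mm3=float(np.prod(spacing)),
    )
    return vol, truth


def default_specs(seed: int = 0) -> list[PhantomSpec]:
    """Four seeded phantoms spanning thin to obese adiposity.

    Subcutaneous ring 4 -> 10 voxels (~8 -> 20 mm) and 5 -> 60 visceral fat
    blobs, so ground-truth visceral volume increases strictly with the
    adiposity level.
    """
    levels = [
        ("thin", (32.0, 26.0), 4.0, 5, (2.5, 3.2), 13.0, (5.0, 8.5, 11.0), 26.0, (17, 126), (108, 124)),
        ("normal", (35.0, 29.0), 6.0, 15, (2.6, 3.6), 14.0, (6.0, 9.0, 11.0), 27.0, (19, 124), (108, 124)),
        ("overweight", (38.0, 32.0), 8.0, 35, (2.8, 3.8), 14.0, (6.0, 9.0, 11.0), 29.0, (21, 122), (108, 122)),
        ("obese", (40.0, 34.0), 10.0, 60, (3.0, 4.0), 14.0, (6.0, 9.0, 10.0), 30.0, (23, 120), (108, 120)),
    ]
    return [
        PhantomSpec(
            name=name,
            torso_semiaxes=semi,
            subcut_thickness=sc,
            n_visceral_blobs=nb,
            blob_radius_range=rr,
            lung_offset_x=lox,
            lung_semiaxes=lsemi,
            lung_center=(50.0, lzc),
            spine_z=spz,
            pelvis_z=pvz,
            seed=seed + i,
        )
        for i, (name, semi, sc, nb, rr, lox, lsemi, lzc, spz, pvz) in enumerate(levels)
    ]
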