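"""Synthetic fluorescence micrograph generator with known ground truth.

Emulates a protein-localization imaging screen: a panel of tagged proteins,
each with a localization archetype (nucleus, cytoplasm, peripheral ring,
punctate, ...), imaged as multi-cell fields with three channels — the tagged
protein ("GFP"), a nuclear marker, and a cytosolic marker. Ground truth
(protein identity, archetype, planted complexes, AND/OR heterogeneity,
cell-cycle stage, foreground template) is recorded per crop so every
downstream analysis stage can be validated against planted structure.

Cells are circles with radius jitter; S, M/A and T stages carry a bud of
increasing size and stage-dependent nuclear morphology, which is what the
cell-cycle classifier learns from. Archetype templates are parametric
(Gaussian blobs, annuli, dots, filaments) rendered in cell-local coordinates;
proteins sharing a ``complex_id`` share archetype parameters exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ARCHETYPES = (
    "nucleus",
    "cytoplasm",
    "peripheral_ring",
    "punctate",
    "nucleolus",
    "nuclear_ring",
    "er_mesh",
    "mito_network",
)

STAGES = ("G1", "S", "MA", "T")
#: resting-population stage frequencies used when sampling cells
STAGE_PROBS = {"G1": 0.35, "S": 0.25, "MA": 0.2, "T": 0.2}
#: bud radius as a fraction of the mother radius, per stage
BUD_FRACTION = {"G1": 0.0, "S": 0.35, "MA": 0.6, "T": 0.85}

CELL_RADIUS = 14.0
RADIUS_JITTER = 1.5
NUCLEUS_SIGMA = 3.5


class ConfigurationError(ValueError):
    pass


@dataclass
class ProteinSpec:
    """Ground-truth description of one tagged protein."""

    protein_id: str
    archetype: str
    abundance: float = 1.0
    heterogeneity: str = "single"  # single | AND | OR
    secondary_archetype: str | None = None
    mixing_fraction: float = 0.0
    complex_id: str | None = None
    cellcycle_dependence: dict[str, str] | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ConfigurationError(f"unknown archetype {self.archetype!r}")
        if not 0.0 <= self.mixing_fraction <= 1.0:
            raise ConfigurationError("mixing fraction must be in [0, 1]")
        if self.heterogeneity == "single" and self.secondary_archetype is not None:
            raise ConfigurationError("single-localizing protein with secondary archetype")
        if self.heterogeneity in ("AND", "OR") and self.secondary_archetype is None:
            raise ConfigurationError(f"{self.heterogeneity} protein needs a secondary archetype")


def _archetype_params(archetype: str, rng: np.random.Generator) -> dict:
    """Per-protein rendering parameters, jittered so same-archetype proteins
    remain distinguishable; complex members copy these exactly."""
    if archetype == "nucleus":
        return {"sigma": float(rng.uniform(3.0, 4.5))}
    if archetype == "nucleolus":
        return {"sigma": float(rng.uniform(1.3, 2.0)), "offset": float(rng.uniform(1.0, 2.5))}
    if archetype == "cytoplasm":
        return {"edge_soft": float(rng.uniform(1.0, 2.5))}
    if archetype == "punctate":
        return {"n_dots": int(rng.integers(4, 9)), "dot_sigma": float(rng.uniform(1.2, 1.9))}
    if archetype == "peripheral_ring":
        return {"width": float(rng.uniform(1.5, 3.0))}
    if archetype == "nuclear_ring":
        return {"width": float(rng.uniform(1.0, 2.0))}
    if archetype == "er_mesh":
        return {"width": float(rng.uniform(1.0, 1.8)), "n_strands": int(rng.integers(3, 6))}
    if archetype == "mito_network":
        return {"n_filaments": int(rng.integers(2, 5)), "sigma": float(rng.uniform(1.0, 1.6))}
    raise ConfigurationError(archetype)


def make_protein_panel(
    n_proteins: int,
    n_complexes: int,
    het_fractions: dict[str, float] | None = None,
    seed: int = 0,
    n_archetypes: int = 4,
    n_cellcycle: int = 0,
    archetypes: tuple[str, ...] | None = None,
) -> list[ProteinSpec]:
    """Build a panel of protein specs with planted complexes and heterogeneity.

    ``het_fractions`` maps "AND"/"OR" to the fraction of the panel with that
    heterogeneity type (counts are rounded). Complex members are
    single-localizing and share archetype parameters exactly. ``n_cellcycle``
    converts that many OR proteins into cell-cycle shuttlers whose archetype
    follows the stage (primary in G1/S/T, secondary in M/A).
    """
    het_fractions = het_fractions or {}
    if archetypes is None:
        archetypes = ARCHETYPES[:n_archetypes]
    n_arch = len(archetypes)
    bad = set(het_fractions) - {"AND", "OR"}
    if bad:
        raise ConfigurationError(f"unknown heterogeneity types {bad}")
    if sum(het_fractions.values()) > 1:
        raise ConfigurationError("heterogeneity fractions sum above 1")
    n_and = int(round(het_fractions.get("AND", 0.0) * n_proteins))
    n_or = int(round(het_fractions.get("OR", 0.0) * n_proteins))
    remaining = n_proteins - n_and - n_or
    if n_complexes > 0 and remaining < 2 * n_complexes:
        raise ConfigurationError(
            f"{remaining} single-localizing proteins cannot host {n_complexes} complexes"
        )
    if n_cellcycle > n_or:
        raise ConfigurationError("n_cellcycle exceeds the number of OR proteins")
    complex_size = 3 if n_complexes and remaining >= 3 * n_complexes else 2
    n_singles = remaining - complex_size * n_complexes

    rng = np.random.default_rng(seed)
    specs: list[ProteinSpec] = []
    pid = 0

    def next_id():
        nonlocal pid
        pid += 1
        return f"P{pid:03d}"

    for ci in range(n_complexes):
        arch = archetypes[ci % n_arch]
        params = _archetype_params(arch, rng)
        # members share abundance as well as archetype parameters: crops of
        # same-complex proteins must be statistically exchangeable
        abundance = float(rng.lognormal(0.0, 0.25))
        for _ in range(complex_size):
            specs.append(
                ProteinSpec(
                    protein_id=next_id(),
                    archetype=arch,
                    abundance=abundance,
                    complex_id=f"C{ci + 1:02d}",
                    params=dict(params),
                )
            )
    for si in range(n_singles):
        arch = archetypes[(n_complexes + si) % n_arch]
        specs.append(
            ProteinSpec(
                protein_id=next_id(),
                archetype=arch,
                abundance=float(rng.lognormal(0.0, 0.25)),
                params=_archetype_params(arch, rng),
            )
        )
    het_list = ["AND"] * n_and + ["OR"] * n_or
    n_or_seen = 0
    for hi, het in enumerate(het_list):
        a1 = archetypes[hi % n_arch]
        a2 = archetypes[(hi + n_arch // 2) % n_arch]
        if a1 == a2:
            a2 = archetypes[(hi + 1) % n_arch]
        cc = None
        if het == "OR":
            n_or_seen += 1
            if n_or_seen > n_or - n_cellcycle:
                # stage-driven shuttler, modelled as nuclear <-> cytoplasmic
                # (present in the nucleus except during metaphase/anaphase)
                a1, a2 = "nucleus", "cytoplasm"
                cc = {"G1": a1, "S": a1, "MA": a2, "T": a1}
        specs.append(
            ProteinSpec(
                protein_id=next_id(),
                archetype=a1,
                abundance=float(rng.lognormal(0.0, 0.25)),
                heterogeneity=het,
                secondary_archetype=a2,
                mixing_fraction=0.5 if het == "AND" else 0.4,
                cellcycle_dependence=cc,
                params=_archetype_params(a1, rng),
            )
        )
        specs[-1].params["secondary"] = _archetype_params(a2, rng)
    return specs


# --------------------------------------------------------------------------
# rendering


def _grid(shape):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return yy.astype(np.float64), xx.astype(np.float64)


def _gauss(yy, xx, cy, cx, sigma):
    return np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))


@dataclass
class _CellGeometry:
    cy: float
    cx: float
    radius: float
    stage: str
    bud_cy: float = 0.0
    bud_cx: float = 0.0
    bud_radius: float = 0.0
    nuclei: list = field(default_factory=list)  # (cy, cx, sigma)


def _make_geometry(cy, cx, radius, stage, rng) -> _CellGeometry:
    geo = _CellGeometry(cy=cy, cx=cx, radius=radius, stage=stage)
    theta = rng.uniform(0, 2 * np.pi)
    bf = BUD_FRACTION[stage]
    if bf > 0:
        br = bf * radius
        dist = radius + 0.55 * br
        geo.bud_cy = cy + dist * np.sin(theta)
        geo.bud_cx = cx + dist * np.cos(theta)
        geo.bud_radius = br
    # nuclear morphology per stage
    off = rng.uniform(-1.5, 1.5, size=2)
    if stage in ("G1", "S"):
        geo.nuclei = [(cy + off[0], cx + off[1], NUCLEUS_SIGMA)]
    elif stage == "MA":
        # elongated/dividing nucleus stretched toward the bud neck
        dy, dx = 2.5 * np.sin(theta), 2.5 * np.cos(theta)
        geo.nuclei = [
            (cy + off[0], cx + off[1], NUCLEUS_SIGMA * 0.85),
            (cy + off[0] + dy, cx + off[1] + dx, NUCLEUS_SIGMA * 0.85),
        ]
    else:  # T: one nucleus in mother, one in bud
        geo.nuclei = [
            (cy + off[0], cx + off[1], NUCLEUS_SIGMA * 0.9),
            (geo.bud_cy, geo.bud_cx, NUCLEUS_SIGMA * 0.75),
        ]
    return geo


def _cell_mask(yy, xx, geo: _CellGeometry, soft=1.5):
    d_mother = np.sqrt((yy - geo.cy) ** 2 + (xx - geo.cx) ** 2) - geo.radius
    mask = 1.0 / (1.0 + np.exp(d_mother / soft))
    if geo.bud_radius > 0:
        d_bud = np.sqrt((yy - geo.bud_cy) ** 2 + (xx - geo.bud_cx) ** 2) - geo.bud_radius
        mask = np.maximum(mask, 1.0 / (1.0 + np.exp(d_bud / soft)))
    return mask


def _render_archetype(yy, xx, geo: _CellGeometry, archetype: str, params: dict, rng):
    """Unit-intensity archetype template in cell-local coordinates."""
    ncy, ncx, nsig = geo.nuclei[0]
    r_cell = np.sqrt((yy - geo.cy) ** 2 + (xx - geo.cx) ** 2)
    if archetype == "nucleus":
        # track the stage-dependent nuclear morphology (scaled per nucleus)
        scale = params.get("sigma", 3.5) / NUCLEUS_SIGMA
        t = sum(
            _gauss(yy, xx, cy, cx, min(scale, 1.05) * s) for cy, cx, s in geo.nuclei
        )
        return np.minimum(t, 1.0)
    if archetype == "nucleolus":
        off = params.get("offset", 1.5)
        ang = rng.uniform(0, 2 * np.pi)
        return _gauss(yy, xx, ncy + off * np.sin(ang), ncx + off * np.cos(ang), params["sigma"])
    if archetype == "cytoplasm":
        mask = _cell_mask(yy, xx, geo, soft=params.get("edge_soft", 1.5))
        nuc = sum(_gauss(yy, xx, cy, cx, s) for cy, cx, s in geo.nuclei)
        return np.clip(mask - 0.85 * np.minimum(nuc, 1.0), 0.0, 1.0)
    if archetype == "punctate":
        t = np.zeros_like(yy)
        for _ in range(params["n_dots"]):
            ang = rng.uniform(0, 2 * np.pi)
            rad = geo.radius * np.sqrt(rng.uniform(0.05, 0.85))
            t += _gauss(yy, xx, geo.cy + rad * np.sin(ang), geo.cx + rad * np.cos(ang),
                        params["dot_sigma"])
        return np.minimum(t, 1.0)
    if archetype == "peripheral_ring":
        ring = np.exp(-((r_cell - geo.radius) ** 2) / (2.0 * params["width"] ** 2))
        if geo.bud_radius > 0:
            r_bud = np.sqrt((yy - geo.bud_cy) ** 2 + (xx - geo.bud_cx) ** 2)
            ring = np.maximum(
                ring, np.exp(-((r_bud - geo.bud_radius) ** 2) / (2.0 * params["width"] ** 2))
            )
        return ring
    if archetype == "nuclear_ring":
        r_nuc = np.sqrt((yy - ncy) ** 2 + (xx - ncx) ** 2)
        return np.exp(-((r_nuc - (nsig + 1.5)) ** 2) / (2.0 * params["width"] ** 2))
    if archetype == "er_mesh":
        r_nuc = np.sqrt((yy - ncy) ** 2 + (xx - ncx) ** 2)
        t = np.exp(-((r_nuc - (nsig + 1.5)) ** 2) / (2.0 * params["width"] ** 2))
        for _ in range(params["n_strands"]):
            ang = rng.uniform(0, 2 * np.pi)
            for rad in np.arange(nsig + 2, geo.radius - 1, 1.0):
                t += 0.6 * _gauss(
                    yy, xx, ncy + rad * np.sin(ang), ncx + rad * np.cos(ang), params["width"]
                )
        return np.minimum(t, 1.0)
    if archetype == "mito_network":
        t = np.zeros_like(yy)
        for _ in range(params["n_filaments"]):
            ang = rng.uniform(0, 2 * np.pi)
            rad = geo.radius * np.sqrt(rng.uniform(0.1, 0.7))
            py, px = geo.cy + rad * np.sin(ang), geo.cx + rad * np.cos(ang)
            heading = rng.uniform(0, 2 * np.pi)
            for _ in range(14):
                t += _gauss(yy, xx, py, px, params["sigma"])
                heading += rng.normal(0, 0.5)
                py += 1.6 * np.sin(heading)
                px += 1.6 * np.cos(heading)
                d = np.hypot(py - geo.cy, px - geo.cx)
                if d > geo.radius - 1.5:  # reflect back inside
                    heading += np.pi
        return np.minimum(t, 1.0)
    raise ConfigurationError(archetype)


def _cell_archetype(spec: ProteinSpec, stage: str, rng) -> tuple[str, dict, str | None]:
    """Archetype(s) this cell expresses: (primary, params, optional AND-partner)."""
    sec_params = spec.params.get("secondary", {})
    if spec.cellcycle_dependence:
        arch = spec.cellcycle_dependence.get(stage, spec.archetype)
        params = spec.params if arch == spec.archetype else sec_params
        return arch, params, None
    if spec.heterogeneity == "OR":
        if rng.uniform() < spec.mixing_fraction:
            return spec.secondary_archetype, sec_params, None
        return spec.archetype, spec.params, None
    if spec.heterogeneity == "AND":
        return spec.archetype, spec.params, spec.secondary_archetype
    return spec.archetype, spec.params, None


def render_field(
    spec: ProteinSpec,
    n_cells: int,
    noise_sd: float = 0.05,
    seed: int = 0,
    field_size: int = 256,
    margin: int = 26,
    min_separation: float = 33.0,
):
    """Render one field of view for one protein.

    Returns ``(field, rows)`` where ``field`` is a (4, H, W) float32 stack —
    pages: GFP, nuclear marker, cytosolic marker, noiseless GFP template
    (ground-truth foreground) — and ``rows`` is a list of per-cell manifest
    dicts (x/y center, stage, archetype expressed).
    """
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    # rejection-sample non-overlapping cell centers
    centers = []
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > 4000:
            raise ConfigurationError(
                f"field of size {field_size} too small for {n_cells} cells"
            )
        cy = rng.uniform(margin, field_size - margin)
        cx = rng.uniform(margin, field_size - margin)
        if all(np.hypot(cy - y, cx - x) >= min_separation for y, x in centers):
            centers.append((cy, cx))

    yy, xx = _grid((field_size, field_size))
    gfp = np.zeros((field_size, field_size))
    nuc = np.zeros_like(gfp)
    cyt = np.zeros_like(gfp)
    stages = list(STAGE_PROBS)
    probs = np.array([STAGE_PROBS[s] for s in stages])
    rows = []
    for ci, (cy, cx) in enumerate(centers):
        stage = stages[rng.choice(len(stages), p=probs)]
        radius = CELL_RADIUS + rng.normal(0, RADIUS_JITTER)
        geo = _make_geometry(cy, cx, radius, stage, rng)
        for ncy, ncx, nsig in geo.nuclei:
            nuc += _gauss(yy, xx, ncy, ncx, nsig)
        cyt += 0.8 * _cell_mask(yy, xx, geo)
        arch, params, and_partner = _cell_archetype(spec, stage, rng)
        t = _render_archetype(yy, xx, geo, arch, params, rng)
        if and_partner is not None:
            # split the protein pool between the two compartments: weights
            # apply to integrated intensity, not template amplitude, so a
            # compact pattern is not swamped by a spatially extended one
            t2 = _render_archetype(
                yy, xx, geo, and_partner, spec.params.get("secondary", {}), rng
            )
            m1, m2 = t.sum(), t2.sum()
            mbar = 0.5 * (m1 + m2)
            if m1 > 0 and m2 > 0:
                t = 0.5 * (t * (mbar / m1)) + 0.5 * (t2 * (mbar / m2))
            else:
                t = 0.5 * t + 0.5 * t2
        gfp += spec.abundance * t
        nuc_cy, nuc_cx = geo.nuclei[0][0], geo.nuclei[0][1]
        rows.append(
            {
                "protein_id": spec.protein_id,
                "x": int(round(nuc_cx)),
                "y": int(round(nuc_cy)),
                "stage": stage,
                "archetype": arch if and_partner is None else f"{arch}+{and_partner}",
            }
        )
    template = gfp.copy()
    if noise_sd > 0:
        gfp = np.clip(gfp + rng.normal(0, noise_sd, gfp.shape), 0, None)
        nuc = np.clip(nuc + rng.normal(0, noise_sd, nuc.shape), 0, None)
        cyt = np.clip(cyt + rng.normal(0, noise_sd, cyt.shape), 0, None)
    field = np.stack([gfp, nuc, cyt, template]).astype(np.float32)
    return field, rows


@dataclass
class SynthDataset:
    """In-memory synthetic dataset: fields plus a complete crop manifest."""

    panel: list[ProteinSpec]
    fields: dict[str, np.ndarray]  # field_key -> (4, H, W)
    manifest: pd.DataFrame

    def spec(self, protein_id: str) -> ProteinSpec:
        return next(s for s in self.panel if s.protein_id == protein_id)

    def write(self, out_dir):
        """Write fields as multi-page TIFF, manifest as CSV, panel as JSON."""
        import tifffile

        out = Path(out_dir)
        (out / "fields").mkdir(parents=True, exist_ok=True)
        for key, arr in self.fields.items():
            tifffile.imwrite(out / "fields" / f"{key}.tif", arr, photometric="minisblack")
        self.manifest.to_csv(out / "manifest.csv", index=False)
        panel = [dataclasses.asdict(s) for s in self.panel]
        (out / "panel.json").write_text(json.dumps(panel, indent=2))


def generate_dataset(
    panel: list[ProteinSpec],
    cells_per_protein: int = 100,
    replicates: int = 2,
    fields_per_replicate: int = 4,
    seed: int = 0,
    noise_sd: float = 0.05,
    field_size: int = 256,
) -> SynthDataset:
    """Render the full screen: every protein across replicates and fields.

    Cells are spread as evenly as possible over ``replicates x
    fields_per_replicate`` fields; replicates differ only in their noise and
    placement realizations, never in archetype parameters.
    """
    if min(cells_per_protein, replicates, fields_per_replicate) < 1:
        raise ConfigurationError("all counts must be >= 1")
    n_fields = replicates * fields_per_replicate
    base = cells_per_protein // n_fields
    extra = cells_per_protein % n_fields
    fields: dict[str, np.ndarray] = {}
    rows = []
    crop_counter = 0
    for pi, spec in enumerate(panel):
        fi = 0
        for rep in range(1, replicates + 1):
            for fld in range(1, fields_per_replicate + 1):
                n_cells = base + (1 if fi < extra else 0)
                fi += 1
                if n_cells == 0:
                    continue
                fseed = int(
                    np.random.SeedSequence([seed, pi, rep, fld]).generate_state(1)[0]
                    % (2**31)
                )
                key = f"{spec.protein_id}_r{rep}_f{fld}"
                field, cell_rows = render_field(
                    spec, n_cells, noise_sd=noise_sd, seed=fseed, field_size=field_size
                )
                fields[key] = field
                for row in cell_rows:
                    crop_counter += 1
                    row.update(
                        crop_id=f"crop{crop_counter:06d}",
                        replicate=rep,
                        field_id=key,
                    )
                    rows.append(row)
    manifest = pd.DataFrame(
        rows,
        columns=["crop_id", "protein_id", "replicate", "field_id", "x", "y", "stage",
                 "archetype"],
    )
    return SynthDataset(panel=panel, fields=fields, manifest=manifest)


def load_dataset(in_dir) -> SynthDataset:
    """Read a dataset previously written with :meth:`SynthDataset.write`."""
    import tifffile

    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.csv")
    fields = {
        p.stem: tifffile.imread(p) for p in sorted((src / "fields").glob("*.tif"))
    }
    panel = [
        ProteinSpec(**{k: v for k, v in d.items()})
        for d in json.loads((src / "panel.json").read_text())
    ]
    return SynthDataset(panel=panel, fields=fields, manifest=manifest)
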