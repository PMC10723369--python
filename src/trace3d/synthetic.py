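"""Synthetic chromatin-tracing data with planted, recoverable structure.

The generator emulates the statistical structure the downstream analyses
assume: spherical nuclei with cell-type-dependent radii, two homologs per
chromosome confined to territories, an autoregressive backbone that yields
spatial-distance decay with genomic distance, iterative relaxation that
plants A/B phase segregation (strength ``lambda``), radial A/B bias
(``rho``) and megadomain condensation (``mu``), plus localization noise and
detection dropout.  A KO genotype attenuates ``lambda`` and ``rho`` by a
factor ``1 - delta``, emulating weakened compartment segregation.

Expression is one gene per genome-class locus with a log-linear Poisson
model coupled to the locus's local A/B density ratio and radial position.

All constants here are test instruments for the analysis pipeline, not
estimates of nuclear biophysics.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    LocusPanel,
    TraceDataset,
    AnnotationTrack,
    ExpressionMatrix,
    track_from_frame,
    write_locus_panel,
    write_traces,
    write_annotation_track,
    write_expression,
    write_json,
)
from .localenv import ab_density_ratio_points

# relaxation calibration: per-iteration step sizes.  The phase step is kept
# moderate (lambda = 1 contracts compartment spread to ~0.36 of initial over
# N_RELAX_ITERS iterations) so that segregation emerges without collapsing
# the nucleus into two point clusters, which would empty the nuclear
# interior and break hull-normalized radial positioning; radial polarization
# is carried by the rho term.
N_RELAX_ITERS = 20
PHASE_STEP = 0.05          # multiplies lambda
RADIAL_STEP_FRAC = 0.04    # multiplies rho * nucleus radius, per iteration
MEGADOMAIN_STEP = 0.15     # multiplies mu
AR_ALPHA = 0.6             # backbone autocorrelation between adjacent loci
AR_SPREAD_FRAC = 0.5       # stationary radial rms of the chain / territory radius


@dataclass(frozen=True)
class CellTypeParams:
    """Per-cell-type simulation knobs (lengths in micrometers)."""

    name: str
    nucleus_radius_um: float = 5.0
    segregation_strength: float = 0.8   # lambda: A/B phase pull
    radial_bias: float = 0.3            # rho: B-to-periphery pull; sign flips invert
    megadomain_strength: float = 0.0    # mu: chromosome-half condensation
    territory_confinement_radius_um: float = 2.0
    base_expression_rate: float = 5.0   # counts/gene/cell at neutral environment
    coupling_ab: float = 1.0            # beta_AB: expression vs log local A/B ratio
    coupling_radial: float = 1.0        # beta_R: expression vs (0.5 - radial position)
    ko_attenuation: float = 0.8         # delta: KO multiplies lambda, rho by 1 - delta

    def __post_init__(self) -> None:
        if not self.nucleus_radius_um > self.territory_confinement_radius_um:
            raise ValueError("nucleus radius must exceed territory confinement radius")
        if self.segregation_strength < 0 or self.megadomain_strength < 0:
            raise ValueError("segregation/megadomain strengths must be >= 0")
        if not 0.0 <= self.ko_attenuation <= 1.0:
            raise ValueError("ko_attenuation must be in [0, 1]")


def default_cell_types() -> list[CellTypeParams]:
    """Stated-world defaults: a large neuron-like and a smaller glia-like type.

    The glia-like type carries megadomain structure (mu > 0), mirroring the
    non-neuronal megadomain prominence the analysis is designed to detect.
    """
    return [
        CellTypeParams(name="neuron", nucleus_radius_um=5.0, segregation_strength=0.8,
                       radial_bias=0.3, megadomain_strength=0.0,
                       territory_confinement_radius_um=2.0),
        CellTypeParams(name="glia", nucleus_radius_um=3.5, segregation_strength=0.8,
                       radial_bias=0.2, megadomain_strength=0.4,
                       territory_confinement_radius_um=1.5),
    ]


@dataclass(frozen=True)
class SimParams:
    n_chrom: int = 5
    loci_per_chrom: int = 60
    spacing_bp: int = 2_500_000
    cell_types: tuple[CellTypeParams, ...] = field(default_factory=lambda: tuple(default_cell_types()))
    n_cells_per_type: int = 300
    n_ko_cells_per_type: int = 0
    n_se_per_type: int = 0
    localization_sigma_um: float = 0.05
    detection_rate: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chrom, self.loci_per_chrom, self.n_cells_per_type) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 < self.detection_rate <= 1.0:
            raise ValueError("detection_rate must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_types"] = [asdict(ct) for ct in self.cell_types]
        return d

    @staticmethod
    def from_dict(d: dict) -> "SimParams":
        d = dict(d)
        d["cell_types"] = tuple(CellTypeParams(**ct) for ct in d["cell_types"])
        return SimParams(**d)


@dataclass
class _CellBlock:
    """Internal noiseless state for one (cell_type, genotype) block."""

    cell_ids: list[str]
    positions: np.ndarray      # (n_cells, n_points, 3), relative to nucleus center
    offsets: np.ndarray        # (n_cells, 3) nucleus centers in the sample frame
    point_locus: np.ndarray    # (n_points,) locus ids
    point_chrom_idx: np.ndarray  # (n_points,) integer chromosome index
    point_homolog: np.ndarray  # (n_points,)
    labels_a: np.ndarray       # (n_points,) bool, A-compartment
    nucleus_radius: float


@dataclass
class GroundTruth:
    """Planted structure sidecar for a simulation."""

    compartment_labels: pd.DataFrame  # cell_type, locus_id, label
    switch_fractions: dict            # (ref_type, other_type) -> realized fraction
    params: SimParams
    block_len_loci: int
    gene_effects: pd.DataFrame | None = None  # gene_id, locus_id, beta_ab, beta_r
    cell_state: dict = field(default_factory=dict, repr=False)

    def labels_for(self, cell_type: str) -> pd.Series:
        sub = self.compartment_labels[self.compartment_labels["cell_type"] == cell_type]
        if sub.empty:
            raise ValueError(f"no planted labels for cell type {cell_type!r}")
        return sub.set_index("locus_id")["label"]


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent named RNG stream derived from the root seed."""
    return np.random.default_rng(np.random.SeedSequence((seed, zlib.crc32(stream.encode()))))


# ---------------------------------------------------------------------------
# Panel and planted compartments
# ---------------------------------------------------------------------------


def generate_panel(params: SimParams) -> LocusPanel:
    """Evenly spaced genome-class loci plus optional super-enhancer loci.

    Genome loci sit at exact ``spacing_bp`` intervals per chromosome; SE loci
    (if requested) are interleaved at one third of a spacing downstream of a
    seeded random subset of genome loci, with round-robin origin cell types.
    """
    rows = []
    width = 50_000
    for c in range(params.n_chrom):
        chrom = f"chr{c + 1}"
        for i in range(params.loci_per_chrom):
            start = params.spacing_bp * (i + 1)
            rows.append((chrom, start, start + width, f"{chrom}_L{i:03d}", "genome", None))
    if params.n_se_per_type:
        rng = _rng(params.seed, "panel_se")
        names = [ct.name for ct in params.cell_types]
        total_se = params.n_se_per_type * len(names)
        genome_slots = [(c, i) for c in range(params.n_chrom) for i in range(params.loci_per_chrom)]
        picks = rng.choice(len(genome_slots), size=total_se, replace=False)
        for k, pick in enumerate(sorted(picks.tolist())):
            c, i = genome_slots[pick]
            chrom = f"chr{c + 1}"
            start = params.spacing_bp * (i + 1) + params.spacing_bp // 3
            rows.append((chrom, start, start + width, f"{chrom}_SE{i:03d}",
                         "super_enhancer", names[k % len(names)]))
    df = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "locus_id",
                                     "panel_class", "origin_cell_type"])
    return LocusPanel(df)


def plant_compartments(panel: LocusPanel, cell_types: list[str] | None = None,
                       block_len_loci: int = 10, switch_fraction: float = 0.15,
                       seed: int = 0, params: SimParams | None = None) -> GroundTruth:
    """Plant alternating A/B blocks and per-type switched loci.

    The first cell type is the reference (alternating blocks of
    ``block_len_loci`` along each chromosome); every other type flips an
    independent seeded random subset of loci with expected fraction
    ``switch_fraction``.  Super-enhancer loci are forced to A in their origin
    cell type and B elsewhere, planting a cell-type-specific active
    environment at those loci.
    """
    if params is not None and cell_types is None:
        cell_types = [ct.name for ct in params.cell_types]
    if not cell_types:
        raise ValueError("cell_types required")
    if not 0.0 <= switch_fraction <= 1.0:
        raise ValueError("switch_fraction must be in [0, 1]")
    per_chrom_counts = panel.df.groupby("chrom").size()
    if block_len_loci > int(per_chrom_counts.max()):
        raise ValueError("block_len_loci exceeds loci per chromosome")

    rng = _rng(seed, "plant_compartments")
    rows = []
    ref_labels: dict[str, str] = {}
    for chrom in panel.chroms:
        sub = panel.loci_for_chrom(chrom)
        genome_pos = 0
        for _, r in sub.iterrows():
            if r["panel_class"] == "super_enhancer":
                ref_labels[r["locus_id"]] = "SE"  # placeholder, resolved per type
                continue
            block = genome_pos // block_len_loci
            ref_labels[r["locus_id"]] = "A" if block % 2 == 0 else "B"
            genome_pos += 1

    switch_fractions: dict = {}
    for t_idx, ct in enumerate(cell_types):
        labels = {}
        non_se = [lid for lid, lab in ref_labels.items() if lab != "SE"]
        if t_idx == 0:
            for lid in non_se:
                labels[lid] = ref_labels[lid]
            switch_fractions[(cell_types[0], ct)] = 0.0
        else:
            flip = rng.random(len(non_se)) < switch_fraction
            n_flipped = 0
            for lid, f in zip(non_se, flip):
                lab = ref_labels[lid]
                if f:
                    lab = "B" if lab == "A" else "A"
                    n_flipped += 1
                labels[lid] = lab
            switch_fractions[(cell_types[0], ct)] = n_flipped / max(len(non_se), 1)
        for lid, lab in ref_labels.items():
            if lab == "SE":
                origin = panel.df.set_index("locus_id").loc[lid, "origin_cell_type"]
                labels[lid] = "A" if origin == ct else "B"
        for _, r in panel.df.iterrows():
            rows.append((ct, r["locus_id"], labels[r["locus_id"]]))

    truth_df = pd.DataFrame(rows, columns=["cell_type", "locus_id", "label"])
    return GroundTruth(compartment_labels=truth_df, switch_fractions=switch_fractions,
                       params=params if params is not None else SimParams(),
                       block_len_loci=block_len_loci)


# ---------------------------------------------------------------------------
# Cell simulation
# ---------------------------------------------------------------------------


def _sample_in_sphere(rng: np.random.Generator, shape, radius: float) -> np.ndarray:
    """Uniform points in a sphere of given radius; shape excludes the final 3."""
    d = rng.normal(size=shape + (3,))
    d /= np.linalg.norm(d, axis=-1, keepdims=True)
    r = radius * rng.random(shape) ** (1.0 / 3.0)
    return d * r[..., None]


def _simulate_block(panel: LocusPanel, labels: pd.Series, ct: CellTypeParams,
                    genotype: str, n_cells: int, params: SimParams,
                    rng: np.random.Generator) -> _CellBlock:
    atten = (1.0 - ct.ko_attenuation) if genotype == "KO" else 1.0
    lam = ct.segregation_strength * atten
    rho = ct.radial_bias * atten
    mu = ct.megadomain_strength
    R = ct.nucleus_radius_um
    R_terr = ct.territory_confinement_radius_um

    # point layout: per chromosome (panel order), two homologs back to back
    chroms = panel.chroms
    point_locus, point_chrom, point_homolog, point_half = [], [], [], []
    chain_id = []  # one chain per (chrom, homolog)
    for c_idx, chrom in enumerate(chroms):
        sub = panel.loci_for_chrom(chrom)
        n_c = len(sub)
        for hom in range(2):
            for i, lid in enumerate(sub["locus_id"]):
                point_locus.append(lid)
                point_chrom.append(c_idx)
                point_homolog.append(hom)
                point_half.append((c_idx * 2 + hom) * 2 + (1 if i >= n_c / 2 else 0))
                chain_id.append(c_idx * 2 + hom)
    point_locus = np.array(point_locus)
    point_chrom = np.array(point_chrom)
    point_homolog = np.array(point_homolog)
    point_half = np.array(point_half)
    chain_id = np.array(chain_id)
    P = len(point_locus)
    n_chains = int(chain_id.max()) + 1

    lab_a = labels.reindex(point_locus).to_numpy() == "A"
    lab_b = ~lab_a

    # territory centers: radius biased by the chromosome's B-label fraction
    # (rho > 0 pushes B-rich chromosomes peripheral)
    chain_chrom = np.array([cid // 2 for cid in range(n_chains)])
    f_b = np.array([lab_b[point_chrom == c].mean() for c in range(len(chroms))])
    max_center_r = max(R - R_terr, 1e-6)
    u = rng.random((n_cells, n_chains))
    base_r = max_center_r * u ** (1.0 / 3.0)
    shift = rho * (f_b[chain_chrom] - 0.5)[None, :] * max_center_r
    center_r = np.clip(base_r + shift, 0.0, max_center_r)
    dirs = rng.normal(size=(n_cells, n_chains, 3))
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    centers = dirs * center_r[..., None]

    # AR(1) backbone per chain, confined to the territory sphere
    sd_axis = AR_SPREAD_FRAC * R_terr / np.sqrt(3.0)
    step_sd = sd_axis * np.sqrt(1.0 - AR_ALPHA ** 2)
    pos = np.empty((n_cells, P, 3))
    chain_points = [np.flatnonzero(chain_id == cid) for cid in range(n_chains)]
    innov = rng.normal(size=(n_cells, P, 3))
    for cid, pts in enumerate(chain_points):
        c = centers[:, cid, :]  # (n_cells, 3)
        prev = c + sd_axis * innov[:, pts[0], :]
        prev = _confine(prev - c, R_terr) + c
        pos[:, pts[0], :] = prev
        for p in pts[1:]:
            nxt = c + AR_ALPHA * (prev - c) + step_sd * innov[:, p, :]
            nxt = _confine(nxt - c, R_terr) + c
            pos[:, p, :] = nxt
            prev = nxt

    pos = _confine(pos, R)

    # synchronous relaxation: phase pull (lambda), radial bias (rho),
    # megadomain condensation (mu); then re-confine to the nucleus
    n_half = int(point_half.max()) + 1
    half_onehot = np.zeros((n_half, P))
    half_onehot[point_half, np.arange(P)] = 1.0
    half_counts = half_onehot.sum(axis=1)
    for _ in range(N_RELAX_ITERS):
        disp = np.zeros_like(pos)
        if lam > 0 and lab_a.any() and lab_b.any():
            c_a = pos[:, lab_a, :].mean(axis=1, keepdims=True)
            c_b = pos[:, lab_b, :].mean(axis=1, keepdims=True)
            target = np.where(lab_a[None, :, None], c_a, c_b)
            disp += PHASE_STEP * lam * (target - pos)
        if rho != 0.0:
            r = np.linalg.norm(pos, axis=-1, keepdims=True)
            direction = np.divide(pos, r, out=np.zeros_like(pos), where=r > 1e-12)
            sign = np.where(lab_b[None, :, None], 1.0, -1.0)
            step = RADIAL_STEP_FRAC * rho * R * sign
            new_r = np.clip(r + step, 0.0, R)
            disp += direction * (new_r - r)
        if mu > 0:
            half_means = np.einsum("hp,npk->nhk", half_onehot, pos) / half_counts[None, :, None]
            target = half_means[:, point_half, :]
            disp += MEGADOMAIN_STEP * mu * (target - pos)
        pos = _confine(pos + disp, R)

    offsets = rng.uniform(0.0, 100.0, size=(n_cells, 3))
    cell_ids = [f"{ct.name}_{genotype}_{i:04d}" for i in range(n_cells)]
    return _CellBlock(cell_ids=cell_ids, positions=pos, offsets=offsets,
                      point_locus=point_locus, point_chrom_idx=point_chrom,
                      point_homolog=point_homolog, labels_a=lab_a, nucleus_radius=R)


def _confine(x: np.ndarray, radius: float) -> np.ndarray:
    """Radially project points outside a centered sphere back to its surface."""
    r = np.linalg.norm(x, axis=-1, keepdims=True)
    scale = np.where(r > radius, radius / np.maximum(r, 1e-300), 1.0)
    return x * scale


def simulate_cells(params: SimParams, truth: GroundTruth) -> TraceDataset:
    """Simulate a TraceDataset; noiseless per-cell state is retained in ``truth``.

    For every cell type, ``n_cells_per_type`` WT cells are generated plus
    ``n_ko_cells_per_type`` KO cells with lambda and rho attenuated by
    ``1 - ko_attenuation``.
    """
    panel = generate_panel(params)
    chrom_names = panel.chroms
    cells_rows, obs_frames = [], []
    truth.cell_state = {}
    for ct in params.cell_types:
        labels = truth.labels_for(ct.name)
        blocks = [("WT", params.n_cells_per_type)]
        if params.n_ko_cells_per_type > 0:
            blocks.append(("KO", params.n_ko_cells_per_type))
        for genotype, n_cells in blocks:
            rng = _rng(params.seed, f"placement:{ct.name}:{genotype}")
            block = _simulate_block(panel, labels, ct, genotype, n_cells, params, rng)
            truth.cell_state[(ct.name, genotype)] = block

            noise_rng = _rng(params.seed, f"noise:{ct.name}:{genotype}")
            drop_rng = _rng(params.seed, f"dropout:{ct.name}:{genotype}")
            noisy = (block.positions + block.offsets[:, None, :]
                     + noise_rng.normal(scale=params.localization_sigma_um,
                                        size=block.positions.shape))
            keep = drop_rng.random(block.positions.shape[:2]) < params.detection_rate
            quality = drop_rng.uniform(0.5, 1.0, size=block.positions.shape[:2])

            n_cells_b, P = keep.shape
            cell_idx, pt_idx = np.nonzero(keep)
            obs_frames.append(pd.DataFrame({
                "cell_id": np.array(block.cell_ids)[cell_idx],
                "locus_id": block.point_locus[pt_idx],
                "chrom": np.array(chrom_names)[block.point_chrom_idx[pt_idx]],
                "homolog": block.point_homolog[pt_idx],
                "x_um": noisy[cell_idx, pt_idx, 0],
                "y_um": noisy[cell_idx, pt_idx, 1],
                "z_um": noisy[cell_idx, pt_idx, 2],
                "quality": quality[cell_idx, pt_idx],
            }))
            for cid in block.cell_ids:
                cells_rows.append((cid, ct.name, genotype, "rep1"))

    cells = pd.DataFrame(cells_rows, columns=["cell_id", "cell_type", "genotype", "replicate"])
    observations = pd.concat(obs_frames, ignore_index=True)
    return TraceDataset(panel=panel, cells=cells, observations=observations)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(dataset: TraceDataset, truth: GroundTruth, params: SimParams,
                        sigma_um: float = 1.0
                        ) -> tuple[ExpressionMatrix, dict[str, AnnotationTrack]]:
    """One gene per genome locus; counts couple to the planted chromatin state.

    count ~ Poisson(base_rate * ratio^beta_AB * exp(beta_R * (0.5 - radial)))
    with the local A/B density ratio and radial position computed on the
    noiseless truth positions of each cell.  Returns the expression matrix
    plus per-cell-type RNA and ATAC annotation tracks derived from WT cells.
    """
    panel = dataset.panel
    genome = panel.df[panel.df["panel_class"] == "genome"]
    gene_rows = [(f"g_{lid}", chrom, int((s + e) // 2), 50_000, lid)
                 for chrom, s, e, lid in zip(genome["chrom"], genome["start_bp"],
                                             genome["end_bp"], genome["locus_id"])]
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "tss_chrom", "tss_bp",
                                             "length_bp", "locus_id"])
    gene_locus = genes["locus_id"].to_numpy()

    ct_by_name = {ct.name: ct for ct in params.cell_types}
    all_counts, all_cell_ids = [], []
    latent_by_type: dict[str, list[np.ndarray]] = {}
    for (ct_name, genotype), block in truth.cell_state.items():
        ct = ct_by_name[ct_name]
        rng = _rng(params.seed, f"expression:{ct_name}:{genotype}")
        n_cells, P = block.positions.shape[:2]
        # per-point local A/B ratio and radial position on truth coordinates
        log_ratio = np.zeros((n_cells, P))
        for i in range(n_cells):
            ratio = ab_density_ratio_points(block.positions[i], block.point_chrom_idx,
                                            block.labels_a, lab_b=~block.labels_a,
                                            sigma_um=sigma_um, min_total_weight=0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                lr = np.log(ratio)
            log_ratio[i] = np.where(np.isfinite(lr), lr, 0.0)
        radial = np.linalg.norm(block.positions, axis=-1) / block.nucleus_radius

        # average the two homolog points of each locus
        locus_order = pd.Index(gene_locus)
        pt_gene = locus_order.get_indexer(block.point_locus)
        valid = pt_gene >= 0
        sums_lr = np.zeros((n_cells, len(locus_order)))
        sums_rad = np.zeros((n_cells, len(locus_order)))
        cnt = np.zeros(len(locus_order))
        np.add.at(cnt, pt_gene[valid], 1.0)
        for i in range(n_cells):
            np.add.at(sums_lr[i], pt_gene[valid], log_ratio[i][valid])
            np.add.at(sums_rad[i], pt_gene[valid], radial[i][valid])
        mean_lr = sums_lr / np.maximum(cnt, 1.0)
        mean_rad = sums_rad / np.maximum(cnt, 1.0)

        latent = (np.log(ct.base_expression_rate)
                  + ct.coupling_ab * mean_lr
                  + ct.coupling_radial * (0.5 - mean_rad))
        counts = rng.poisson(np.exp(latent))  # (n_cells, n_genes)
        all_counts.append(counts)
        all_cell_ids.extend(block.cell_ids)
        if genotype == "WT":
            latent_by_type.setdefault(ct_name, []).append(latent)

    counts = np.concatenate(all_counts, axis=0).T  # genes x cells
    counts_df = pd.DataFrame(counts, index=genes["gene_id"].to_numpy(), columns=all_cell_ids)
    counts_df.index.name = "gene_id"
    cells = dataset.cells[dataset.cells["cell_id"].isin(all_cell_ids)].reset_index(drop=True)
    expr = ExpressionMatrix(genes=genes.drop(columns=["locus_id"]), counts=counts_df, cells=cells)

    # per-cell-type tracks from WT latent rates
    track_rng = _rng(params.seed, "tracks")
    rna_rows, atac_rows = [], []
    for ct_name, latents in latent_by_type.items():
        mean_latent = np.concatenate(latents, axis=0).mean(axis=0)
        noise = track_rng.normal(scale=0.1 * max(np.std(mean_latent), 1e-9),
                                 size=mean_latent.shape)
        for lid, lat, nz in zip(gene_locus, mean_latent, noise):
            rna_rows.append((ct_name, lid, float(np.exp(lat))))
            atac_rows.append((ct_name, lid, float(lat + nz)))
    rna = track_from_frame("rna", pd.DataFrame(rna_rows, columns=["cell_type", "locus_id", "value"]))
    atac = track_from_frame("atac", pd.DataFrame(atac_rows, columns=["cell_type", "locus_id", "value"]))

    # per-gene true couplings (shared within a cell type in this model)
    truth.gene_effects = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "locus_id": gene_locus,
        "beta_ab": ct_by_name[params.cell_types[0].name].coupling_ab,
        "beta_r": ct_by_name[params.cell_types[0].name].coupling_radial,
    })
    return expr, {"rna": rna, "atac": atac}


# ---------------------------------------------------------------------------
# Ground-truth sidecars and one-call convenience
# ---------------------------------------------------------------------------


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.compartment_labels.to_csv(out / "compartment_labels.tsv", sep="\t", index=False)
    meta = {
        "params": truth.params.to_dict(),
        "block_len_loci": truth.block_len_loci,
        "switch_fractions": {f"{a}->{b}": v for (a, b), v in truth.switch_fractions.items()},
    }
    write_json(meta, out / "truth.json")
    if truth.gene_effects is not None:
        truth.gene_effects.to_csv(out / "gene_effects.tsv", sep="\t", index=False)


def read_ground_truth(in_dir: str | Path) -> GroundTruth:
    in_dir = Path(in_dir)
    labels = pd.read_csv(in_dir / "compartment_labels.tsv", sep="\t",
                         dtype={"cell_type": str, "locus_id": str, "label": str})
    with open(in_dir / "truth.json") as fh:
        meta = json.load(fh)
    sf = {}
    for key, v in meta["switch_fractions"].items():
        a, b = key.split("->")
        sf[(a, b)] = v
    gene_effects = None
    ge_path = in_dir / "gene_effects.tsv"
    if ge_path.exists():
        gene_effects = pd.read_csv(ge_path, sep="\t")
    return GroundTruth(compartment_labels=labels, switch_fractions=sf,
                       params=SimParams.from_dict(meta["params"]),
                       block_len_loci=meta["block_len_loci"], gene_effects=gene_effects)


def simulate(params: SimParams, block_len_loci: int = 10, switch_fraction: float = 0.15,
             with_expression: bool = True):
    """Panel + truth + traces (+ expression and tracks) in one call."""
    panel = generate_panel(params)
    block_len_loci = min(block_len_loci, params.loci_per_chrom)
    truth = plant_compartments(panel, [ct.name for ct in params.cell_types],
                               block_len_loci=block_len_loci,
                               switch_fraction=switch_fraction,
                               seed=params.seed, params=params)
    dataset = simulate_cells(params, truth)
    if not with_expression:
        return panel, truth, dataset, None, None
    expr, tracks = simulate_expression(dataset, truth, params)
    return panel, truth, dataset, expr, tracks


def write_simulation(out_dir: str | Path, params: SimParams, **sim_kwargs) -> None:
    """Emit panel.bed, cells.tsv, observations.tsv, tracks/, expression/, truth/."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, truth, dataset, expr, tracks = simulate(params, **sim_kwargs)
    write_locus_panel(panel, out / "panel.bed")
    write_traces(dataset, out / "cells.tsv", out / "observations.tsv")
    write_ground_truth(truth, out / "truth")
    if expr is not None:
        (out / "tracks").mkdir(exist_ok=True)
        for name, track in tracks.items():
            write_annotation_track(track, out / "tracks" / f"{name}.tsv")
        (out / "expression").mkdir(exist_ok=True)
        write_expression(expr, out / "expression" / "genes.tsv",
                         out / "expression" / "counts.tsv")
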