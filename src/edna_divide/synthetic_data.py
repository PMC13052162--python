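"""Synthetic riverscape and eDNA metabarcoding dataset generator with known ground truth.

The generator emulates the study system downstream stages are built for: a coastal
mountain ridge (the main drainage divide, MDD) separating small "ligurian" basins
draining west from "adriatic" basins draining east. Fish species carry basin-structured
cytochrome-b haplotype variation produced by a stepping-stone mutation model along the
basin graph, so that geographic distance and genetic dissimilarity are positively
coupled (isolation by distance) by construction.

On top of the true haplotypes the generator plants, with known identities, the
artefact classes a metabarcoding quality filter must remove:

- NUMTs — copies of real haplotypes with an in-frame stop codon plus ~2% substitutions;
- singleton ASVs occurring in exactly one sample;
- low-read ASVs with fewer than 10 reads overall;
- contaminants present in negative controls at counts exceeding any field sample;
- marine fish ASVs labelled with excluded marine families.

Everything is deterministic per seed and returned together with a
:class:`GroundTruth` listing which ASV belongs to which class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .rasters import AsciiGrid, write_ascii_grid

#: Stop codons of the vertebrate mitochondrial genetic code.
MITO_STOP_CODONS = ("TAA", "TAG", "AGA", "AGG")

#: Marine fish families excluded from the freshwater analyses.
MARINE_FAMILIES = (
    "Clupeidae", "Mugilidae", "Sparidae", "Moronidae", "Engraulidae",
    "Scombridae", "Xiphiidae", "Carangidae", "Istiophoridae",
)

# Freshwater fish taxa of the Ligurian/Po transition zone used as default labels.
FRESHWATER_TAXA = (
    ("Actinopterygii", "Cypriniformes", "Leuciscidae", "Telestes", "Telestes muticellus"),
    ("Actinopterygii", "Cypriniformes", "Leuciscidae", "Phoxinus", "Phoxinus lumaireul"),
    ("Actinopterygii", "Cypriniformes", "Cyprinidae", "Barbus", "Barbus caninus"),
    ("Actinopterygii", "Salmoniformes", "Salmonidae", "Salmo", "Salmo trutta"),
    ("Actinopterygii", "Perciformes", "Cottidae", "Cottus", "Cottus gobio"),
    ("Actinopterygii", "Anguilliformes", "Anguillidae", "Anguilla", "Anguilla anguilla"),
    ("Actinopterygii", "Cypriniformes", "Leuciscidae", "Squalius", "Squalius squalus"),
    ("Actinopterygii", "Cypriniformes", "Nemacheilidae", "Barbatula", "Barbatula barbatula"),
)

EARTH_KM_PER_DEG = 111.195


class ConfigurationError(ValueError):
    """A riverscape scenario that cannot host the requested basins."""


class GeneratorConflict(ValueError):
    """Planted artefact classes collided on a single ASV sequence."""


# ---------------------------------------------------------------------------
# scenario and riverscape
# ---------------------------------------------------------------------------

@dataclass
class RiverscapeScenario:
    """Geometry of the synthetic two-sided drainage divide.

    The grid is planar with square cells of ``cell_size_km``. A north-south ridge
    at ``ridge_col_fraction`` of the width separates the two sides; the outermost
    ``sea_margin_cells`` columns on each side are sea.
    """

    grid_shape: tuple[int, int] = (60, 80)
    cell_size_km: float = 1.0
    ridge_col_fraction: float = 0.5
    n_basins_per_side: int = 5
    sea_margin_cells: int = 3
    seed: int = 0
    ridge_elevation_m: float = 2400.0
    origin_lon: float = 8.0
    origin_lat: float = 44.0


@dataclass
class Riverscape:
    dem: AsciiGrid
    rivers: AsciiGrid
    sea: AsciiGrid
    basins: pd.DataFrame  # basin_id, side, row, col, lon, lat
    ridge_col: int


def generate_riverscape(scenario: RiverscapeScenario) -> Riverscape:
    """Build DEM, river and sea rasters plus a basin table for a scenario.

    Each basin is one river running from a headwater near the ridge to the sea
    margin on its own side; no river crosses the ridge. Elevation is maximal on
    the ridge column and decreases monotonically toward each sea margin.
    """
    rows, cols = scenario.grid_shape
    n = scenario.n_basins_per_side
    margin = scenario.sea_margin_cells
    if rows < 20 or cols < 20:
        raise ConfigurationError(f"grid {rows}x{cols} below the 20x20 minimum")
    if n < 1:
        raise ConfigurationError("need at least one basin per side")
    if rows - 4 < 3 * n:
        raise ConfigurationError(f"{rows} rows cannot host {n} basins per side")
    if cols < 2 * margin + 10:
        raise ConfigurationError(f"{cols} columns too narrow for sea margin {margin}")

    rng = np.random.default_rng(scenario.seed)
    ridge_col = int(round(scenario.ridge_col_fraction * (cols - 1)))
    if not (margin + 4 <= ridge_col <= cols - margin - 5):
        raise ConfigurationError("ridge column falls inside a sea margin")

    sea = np.zeros((rows, cols))
    if margin > 0:
        sea[:, :margin] = 1.0
        sea[:, cols - margin:] = 1.0

    # Linear slopes from sea level at each margin up to the ridge crest.
    dem = np.zeros((rows, cols))
    col_idx = np.arange(cols, dtype=float)
    west = np.clip((col_idx - margin) / (ridge_col - margin), 0.0, None)
    east = np.clip((cols - 1 - margin - col_idx) / (cols - 1 - margin - ridge_col), 0.0, None)
    profile = np.minimum(west, east) * scenario.ridge_elevation_m
    profile[sea[0] > 0] = 0.0
    dem[:] = profile

    # Evenly spaced basin rows with a small deterministic jitter.
    base_rows = np.round(np.linspace(2, rows - 3, n)).astype(int)
    jitter = rng.integers(-1, 2, size=n)
    basin_rows = np.clip(base_rows + jitter, 1, rows - 2)
    basin_rows = np.unique(basin_rows)
    while len(basin_rows) < n:  # jitter collisions: fall back to the even grid
        basin_rows = base_rows
        break

    rivers = np.zeros((rows, cols))
    records = []
    cell = scenario.cell_size_km
    coslat = math.cos(math.radians(scenario.origin_lat))
    for i, r in enumerate(sorted(basin_rows)):
        for side, cols_span, bid in (
            ("ligurian", range(margin, ridge_col - 1), f"L{i + 1}"),
            ("adriatic", range(ridge_col + 2, cols - margin), f"A{i + 1}"),
        ):
            span = list(cols_span)
            rivers[r, span] = 1.0
            c = span[len(span) // 2]
            records.append({
                "basin_id": bid,
                "side": side,
                "row": int(r),
                "col": int(c),
                "lon": scenario.origin_lon + c * cell / (EARTH_KM_PER_DEG * coslat),
                "lat": scenario.origin_lat + (rows - 1 - r) * cell / EARTH_KM_PER_DEG,
            })
    basins = pd.DataFrame.from_records(records)
    # order alongshore (north to south) within side, ligurian first
    basins = pd.concat(
        [
            basins[basins.side == "ligurian"].sort_values("row"),
            basins[basins.side == "adriatic"].sort_values("row"),
        ],
        ignore_index=True,
    )

    def as_grid(a: np.ndarray) -> AsciiGrid:
        return AsciiGrid(data=a, cellsize=cell)

    return Riverscape(
        dem=as_grid(dem), rivers=as_grid(rivers), sea=as_grid(sea),
        basins=basins, ridge_col=ridge_col,
    )


def basin_graph(
    basins: pd.DataFrame,
    cross_links: tuple[int, ...] = (0,),
    cross_weight: float = 0.25,
) -> nx.Graph:
    """Stepping-stone graph over basins: an alongshore chain per side, plus
    low-weight cross-divide edges at the indices in ``cross_links`` (0 = the
    northernmost pair, emulating mixing across the divide at one end).
    Edge weights scale the expected number of mutational steps.
    """
    g = nx.Graph()
    for side in ("ligurian", "adriatic"):
        ids = basins.loc[basins.side == side].sort_values("row").basin_id.tolist()
        g.add_nodes_from(ids)
        for a, b in zip(ids, ids[1:]):
            g.add_edge(a, b, weight=1.0)
    lig = basins.loc[basins.side == "ligurian"].sort_values("row").basin_id.tolist()
    adr = basins.loc[basins.side == "adriatic"].sort_values("row").basin_id.tolist()
    for i in cross_links:
        if i < len(lig) and i < len(adr):
            g.add_edge(lig[i], adr[i], weight=cross_weight)
    return g


# ---------------------------------------------------------------------------
# sequences and haplotype evolution
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in MITO_STOP_CODONS
]


def random_coding_sequence(length: int, rng: np.random.Generator) -> str:
    """Random in-frame DNA with no vertebrate-mitochondrial stop codon."""
    n_codons, rem = divmod(length, 3)
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    tail = "".join(rng.choice(_BASES, size=rem)) if rem else ""
    return "".join(_NONSTOP_CODONS[i] for i in idx) + tail


def mutate_sequence(
    seq: str, n_substitutions: int, rng: np.random.Generator, avoid_stops: bool = True
) -> str:
    """Apply substitutions at uniform positions; optionally never create an
    in-frame stop codon (frame anchored at position 0)."""
    s = list(seq)
    for _ in range(n_substitutions):
        for _attempt in range(100):
            pos = int(rng.integers(0, len(s)))
            old = s[pos]
            new = str(rng.choice(_BASES[_BASES != old]))
            s[pos] = new
            if not avoid_stops:
                break
            cstart = 3 * (pos // 3)
            codon = "".join(s[cstart:cstart + 3])
            if len(codon) < 3 or codon not in MITO_STOP_CODONS:
                break
            s[pos] = old  # would create a stop: retry elsewhere
        else:  # pragma: no cover - virtually impossible
            s[pos] = old
    return "".join(s)


@dataclass
class SpeciesModel:
    """One fish species: marker ancestor, mutation rate, occupied basins, read model.

    ``per_step_mutations`` is the Poisson mean number of substitutions applied per
    unit edge weight of the basin graph (stepping-stone model). Read counts per
    occupied sample are negative-binomial with ``reads_mean``/``reads_dispersion``;
    they only matter upstream of pooling since all analyses are occurrence-based.
    """

    species_name: str
    ancestral_sequence: str
    per_step_mutations: float
    occupancy: tuple[str, ...]
    reads_mean: float = 5000.0
    reads_dispersion: float = 2.0
    taxon_path: tuple[str, str, str, str, str] = ("Actinopterygii", "", "", "", "")

    def __post_init__(self) -> None:
        if set(self.ancestral_sequence) - set("ACGT"):
            raise ValueError("ancestral sequence must be plain A/C/G/T")
        if self.per_step_mutations < 0:
            raise ValueError("per_step_mutations must be >= 0")
        if not self.occupancy:
            raise ValueError("occupancy must be non-empty")


def evolve_haplotypes(
    model: SpeciesModel,
    graph: nx.Graph,
    seed: int,
    root: str | None = None,
    retain_parent_prob: float = 0.0,
) -> dict[str, set[str]]:
    """Stepping-stone haplotype evolution over the occupied basin graph.

    A breadth-first tree is grown from ``root`` (default: first occupied basin in
    sorted order); the root carries the ancestral sequence and every tree edge
    applies ``Poisson(per_step_mutations * edge_weight)`` substitutions, so the
    expected mismatch between basins grows with graph distance. With probability
    ``retain_parent_prob`` a basin additionally retains its parent's haplotype
    (shared haplotypes across neighbouring basins).
    """
    occ = [b for b in model.occupancy if b in graph]
    if len(occ) != len(model.occupancy):
        missing = set(model.occupancy) - set(occ)
        raise ValueError(f"occupied basins absent from graph: {sorted(missing)}")
    sub = graph.subgraph(occ)
    if len(occ) > 1 and not nx.is_connected(sub):
        raise ValueError(f"basin graph not connected over occupancy of {model.species_name}")
    rng = np.random.default_rng(seed)
    root = root or sorted(occ)[0]
    haplos: dict[str, set[str]] = {root: {model.ancestral_sequence}}
    lineage: dict[str, str] = {root: model.ancestral_sequence}
    for parent, child in nx.bfs_edges(sub, root, sort_neighbors=sorted):
        lam = model.per_step_mutations * sub.edges[parent, child].get("weight", 1.0)
        n_mut = int(rng.poisson(lam))
        derived = mutate_sequence(lineage[parent], n_mut, rng)
        lineage[child] = derived
        haplos[child] = {derived}
        if retain_parent_prob > 0 and rng.random() < retain_parent_prob:
            haplos[child].add(lineage[parent])
    return haplos


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted identities of every ASV in a synthetic dataset."""

    planted_numt_ids: list[str]
    planted_contaminant_ids: list[str]
    planted_noise_ids: list[str]
    planted_marine_ids: list[str]
    true_haplotype_of_asv: dict[str, tuple[str, tuple[str, ...]]]
    expected_survivor_count: int

    def __post_init__(self) -> None:
        lists = [
            set(self.planted_numt_ids), set(self.planted_contaminant_ids),
            set(self.planted_noise_ids), set(self.planted_marine_ids),
        ]
        total = sum(len(s) for s in lists)
        if len(set().union(*lists)) != total:
            raise GeneratorConflict("planted artefact classes overlap")

    def to_json(self) -> str:
        return json.dumps({
            "planted_numt_ids": self.planted_numt_ids,
            "planted_contaminant_ids": self.planted_contaminant_ids,
            "planted_noise_ids": self.planted_noise_ids,
            "planted_marine_ids": self.planted_marine_ids,
            "true_haplotype_of_asv": {
                k: {"species": sp, "basins": list(bs)}
                for k, (sp, bs) in self.true_haplotype_of_asv.items()
            },
            "expected_survivor_count": self.expected_survivor_count,
        }, indent=1)


@dataclass
class SyntheticDataset:
    """A complete post-denoising metabarcoding dataset with ground truth."""

    counts: pd.DataFrame            # samples (rows, incl. controls) x ASVs
    is_control: pd.Series           # bool per sample
    sequences: dict[str, str]       # asv_id -> DNA
    taxonomy: pd.DataFrame          # asv_id, taxon_path, confidence
    metadata: pd.DataFrame          # sample_id, site, basin, side, year, is_control
    ground_truth: GroundTruth
    riverscape: Riverscape
    reference_cds: str              # in-frame marker reference for the NUMT screen
    species_models: list[SpeciesModel] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.rename_axis("sample_id").to_csv(outdir / "asv_table.tsv", sep="\t")
        with open(outdir / "asv_sequences.fasta", "w") as fh:
            for aid, seq in self.sequences.items():
                fh.write(f">{aid}\n{seq}\n")
        self.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        with open(outdir / "reference_cds.fasta", "w") as fh:
            fh.write(">synthetic_marker_reference\n" + self.reference_cds + "\n")
        with open(outdir / "ground_truth.json", "w") as fh:
            fh.write(self.ground_truth.to_json())
        write_ascii_grid(self.riverscape.dem, outdir / "dem.asc")
        write_ascii_grid(self.riverscape.rivers, outdir / "rivers.asc")
        write_ascii_grid(self.riverscape.sea, outdir / "sea.asc")
        self.riverscape.basins.to_csv(outdir / "basins.tsv", sep="\t", index=False)


def default_species_models(
    basins: pd.DataFrame,
    rng: np.random.Generator,
    n_species: int = 6,
    n_single_basin_species: int = 1,
    sequence_length: int = 420,
    per_step_mutations: float = 2.0,
    divergence: float = 0.08,
) -> tuple[list[SpeciesModel], str]:
    """Species models sharing one marker ancestor (all amplicons homologous).

    Most species are widespread (every basin on both sides, connected through the
    northern cross-divide link); one species is range-restricted to alongshore
    prefixes of both chains, and single-basin species sit in one random basin —
    so no basin is ever empty while occupancy still varies between species.
    Returns the models and the marker reference sequence.
    """
    reference = random_coding_sequence(sequence_length, rng)
    lig = basins.loc[basins.side == "ligurian"].sort_values("row").basin_id.tolist()
    adr = basins.loc[basins.side == "adriatic"].sort_values("row").basin_id.tolist()
    models = []
    n_div = max(1, round(divergence * sequence_length))
    for i in range(n_species):
        taxon = FRESHWATER_TAXA[i % len(FRESHWATER_TAXA)]
        name = taxon[4] if i < len(FRESHWATER_TAXA) else f"{taxon[3]} sp{i}"
        ancestral = mutate_sequence(reference, n_div, rng)
        if i >= n_species - n_single_basin_species:
            occ: tuple[str, ...] = (str(rng.choice(lig + adr)),)
        elif i == n_species - n_single_basin_species - 1 and min(len(lig), len(adr)) >= 2:
            # one range-restricted species on alongshore prefixes of both chains
            k_l = int(rng.integers(2, len(lig) + 1))
            k_a = int(rng.integers(2, len(adr) + 1))
            occ = tuple(lig[:k_l] + adr[:k_a])
        else:
            occ = tuple(lig + adr)
        models.append(SpeciesModel(
            species_name=name,
            ancestral_sequence=ancestral,
            per_step_mutations=per_step_mutations,
            occupancy=occ,
            taxon_path=taxon,
        ))
    return models, reference


def synthesize_dataset(
    scenario: RiverscapeScenario | None = None,
    species_models: list[SpeciesModel] | None = None,
    *,
    n_species: int = 6,
    n_single_basin_species: int = 1,
    n_samples_per_basin: int = 2,
    n_controls: int = 8,
    n_numts: int = 20,
    n_singletons: int = 15,
    n_low_read: int = 10,
    n_contaminants: int = 5,
    n_marine: int = 5,
    cross_links: tuple[int, ...] = (0,),
    cross_weight: float = 0.25,
    retain_parent_prob: float = 0.25,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate riverscape, haplotypes, read counts and planted artefacts.

    Deterministic per ``seed``. True haplotypes are guaranteed to pass every
    quality filter by construction (stop-free, in >= 2 samples, >= 10 reads,
    absent from controls, freshwater taxonomy); each planted artefact class fails
    exactly its targeted filter.
    """
    if n_controls < 1:
        raise ValueError("at least one negative control is required")
    scenario = scenario or RiverscapeScenario(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5EDA)))
    scape = generate_riverscape(scenario)
    graph = basin_graph(scape.basins, cross_links=cross_links, cross_weight=cross_weight)

    reference: str
    if species_models is None:
        species_models, reference = default_species_models(
            scape.basins, rng, n_species=n_species,
            n_single_basin_species=n_single_basin_species,
        )
    else:
        reference = species_models[0].ancestral_sequence

    # sample layout
    meta_rows = []
    for _, b in scape.basins.iterrows():
        for k in range(n_samples_per_basin):
            meta_rows.append({
                "sample_id": f"{b.basin_id}_s{k + 1}",
                "site": f"{b.basin_id}_site{k + 1}",
                "basin": b.basin_id,
                "side": b.side,
                "year": 2021 + (k % 2),
                "is_control": False,
            })
    for j in range(n_controls):
        meta_rows.append({
            "sample_id": f"CTRL{j + 1}", "site": "", "basin": "", "side": "",
            "year": 2021, "is_control": True,
        })
    metadata = pd.DataFrame(meta_rows)
    samples = metadata.sample_id.tolist()
    field_samples = metadata.loc[~metadata.is_control, "sample_id"].tolist()
    samples_of_basin = {
        b: metadata.loc[metadata.basin == b, "sample_id"].tolist()
        for b in scape.basins.basin_id
    }

    def nb_counts(model_mean: float, disp: float, size: int) -> np.ndarray:
        p = disp / (disp + model_mean)
        return np.maximum(1, rng.negative_binomial(disp, p, size=size))

    seq_to_id: dict[str, str] = {}
    seq_owner: dict[str, str] = {}           # sequence -> species (true haplotypes)
    counts: dict[str, dict[str, int]] = {}   # asv_id -> {sample: reads}
    taxonomy_rows: list[dict] = []
    true_map: dict[str, tuple[str, set[str]]] = {}
    n_asv = 0

    def new_id() -> str:
        nonlocal n_asv
        n_asv += 1
        return f"ASV_{n_asv:04d}"

    def register(seq: str, taxon: tuple[str, ...], confidence: float = 95.0) -> str:
        if seq in seq_to_id:
            raise GeneratorConflict("distinct planted classes produced one sequence")
        aid = new_id()
        seq_to_id[seq] = aid
        counts[aid] = {}
        taxonomy_rows.append({
            "asv_id": aid, "taxon_path": ";".join(taxon), "confidence": confidence,
        })
        return aid

    # --- true haplotypes ---------------------------------------------------
    for si, model in enumerate(species_models):
        hap_seed = int(rng.integers(0, 2**31 - 1))
        haplos = evolve_haplotypes(
            model, graph, seed=hap_seed, retain_parent_prob=retain_parent_prob,
        )
        for basin in sorted(haplos):
            for seq in sorted(haplos[basin]):
                if seq in seq_to_id:
                    if seq_owner.get(seq) != model.species_name:
                        raise GeneratorConflict("haplotype shared across species")
                    aid = seq_to_id[seq]
                else:
                    aid = register(seq, model.taxon_path)
                    seq_owner[seq] = model.species_name
                    true_map[aid] = (model.species_name, set())
                true_map[aid][1].add(basin)
                basin_samples = samples_of_basin[basin]
                reads = nb_counts(model.reads_mean, model.reads_dispersion,
                                  len(basin_samples))
                for smp, r in zip(basin_samples, reads):
                    counts[aid][smp] = counts[aid].get(smp, 0) + int(r)

    true_ids = list(true_map)
    if not true_ids:
        raise GeneratorConflict("no true haplotypes generated")

    def unique_sequence(maker) -> str:
        for _ in range(1000):
            seq = maker()
            if seq not in seq_to_id:
                return seq
        raise GeneratorConflict("could not generate a unique sequence")

    # --- NUMTs: real haplotype + 2% substitutions + an in-frame stop -------
    numt_ids = []
    for _ in range(n_numts):
        src = str(rng.choice(true_ids))
        src_seq = next(s for s, a in seq_to_id.items() if a == src)

        def make_numt(src_seq=src_seq) -> str:
            s = mutate_sequence(src_seq, max(1, round(0.02 * len(src_seq))), rng,
                                avoid_stops=True)
            codon_idx = int(rng.integers(10, len(s) // 3))
            stop = MITO_STOP_CODONS[int(rng.integers(0, 4))]
            return s[:3 * codon_idx] + stop + s[3 * codon_idx + 3:]

        seq = unique_sequence(make_numt)
        sp = true_map[src][0]
        taxon = next(m.taxon_path for m in species_models if m.species_name == sp)
        aid = register(seq, taxon, confidence=70.0)
        numt_ids.append(aid)
        for basin in sorted(true_map[src][1]):
            basin_samples = samples_of_basin[basin]
            reads = nb_counts(2000.0, 2.0, len(basin_samples))
            for smp, r in zip(basin_samples, reads):
                counts[aid][smp] = int(r)

    # --- noise: singletons and low-read ASVs --------------------------------
    # artefact sequences are divergent variants of the shared marker (every
    # amplicon from one primer pair is homologous), kept stop-free in frame
    noise_ids = []
    L = len(reference)

    def divergent_variant() -> str:
        return mutate_sequence(reference, max(1, round(0.15 * L)), rng)

    for _ in range(n_singletons):
        seq = unique_sequence(divergent_variant)
        taxon = FRESHWATER_TAXA[int(rng.integers(0, len(FRESHWATER_TAXA)))]
        aid = register(seq, taxon, confidence=65.0)
        noise_ids.append(aid)
        smp = field_samples[int(rng.integers(0, len(field_samples)))]
        counts[aid][smp] = int(rng.integers(50, 2000))
    for _ in range(n_low_read):
        seq = unique_sequence(divergent_variant)
        taxon = FRESHWATER_TAXA[int(rng.integers(0, len(FRESHWATER_TAXA)))]
        aid = register(seq, taxon, confidence=65.0)
        noise_ids.append(aid)
        k = int(rng.integers(2, 4))
        picks = rng.choice(len(field_samples), size=k, replace=False)
        for p in picks:
            counts[aid][field_samples[p]] = int(rng.integers(1, 9 // k + 1))

    # --- contaminants: dominated by negative-control reads ------------------
    contaminant_ids = []
    control_samples = metadata.loc[metadata.is_control, "sample_id"].tolist()
    for _ in range(n_contaminants):
        seq = unique_sequence(divergent_variant)
        taxon = FRESHWATER_TAXA[int(rng.integers(0, len(FRESHWATER_TAXA)))]
        aid = register(seq, taxon, confidence=80.0)
        contaminant_ids.append(aid)
        c_total = int(rng.integers(200, 601))
        k_ctrl = int(rng.integers(1, len(control_samples) + 1))
        picks = rng.choice(len(control_samples), size=k_ctrl, replace=False)
        split = rng.multinomial(c_total, np.ones(k_ctrl) / k_ctrl)
        for p, c in zip(picks, split):
            if c > 0:
                counts[aid][control_samples[p]] = int(c)
        n_field = max(1, int(0.3 * len(field_samples)))
        fpicks = rng.choice(len(field_samples), size=n_field, replace=False)
        for p in fpicks:
            counts[aid][field_samples[p]] = int(rng.integers(1, max(2, c_total // 2)))

    # --- marine taxa ---------------------------------------------------------
    marine_ids = []
    for m in range(n_marine):
        seq = unique_sequence(divergent_variant)
        fam = MARINE_FAMILIES[m % len(MARINE_FAMILIES)]
        genus = fam[:-4]
        taxon = ("Actinopterygii", "Incertae", fam, genus, f"{genus} maris")
        aid = register(seq, taxon, confidence=90.0)
        marine_ids.append(aid)
        basins_pick = rng.choice(scape.basins.basin_id.tolist(), size=2, replace=False)
        for basin in basins_pick:
            for smp in samples_of_basin[basin]:
                counts[aid][smp] = int(nb_counts(1000.0, 2.0, 1)[0])

    # --- assemble ------------------------------------------------------------
    asv_ids = [f"ASV_{i + 1:04d}" for i in range(n_asv)]
    mat = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"),
                       columns=asv_ids, dtype=int)
    for aid, per_sample in counts.items():
        for smp, r in per_sample.items():
            mat.loc[smp, aid] = r
    is_control = metadata.set_index("sample_id").is_control.astype(bool)

    gt = GroundTruth(
        planted_numt_ids=numt_ids,
        planted_contaminant_ids=contaminant_ids,
        planted_noise_ids=noise_ids,
        planted_marine_ids=marine_ids,
        true_haplotype_of_asv={
            k: (sp, tuple(sorted(bs))) for k, (sp, bs) in true_map.items()
        },
        expected_survivor_count=len(true_map),
    )
    sequences = {aid: seq for seq, aid in sorted(seq_to_id.items(), key=lambda kv: kv[1])}
    return SyntheticDataset(
        counts=mat,
        is_control=is_control,
        sequences=sequences,
        taxonomy=pd.DataFrame(taxonomy_rows),
        metadata=metadata,
        ground_truth=gt,
        riverscape=scape,
        reference_cds=reference,
        species_models=species_models,
    )
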