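"""Synthetic screens, ontologies and interactomes with known ground truth.

Every generator is a pure function of its parameters and seed and emits
exactly the text dialects the analysis stages consume, plus a truth
object, so the whole pipeline is testable without any download.

The screen generator emulates the structure the normalization stage is
designed to remove: multiplicative per-position plate factors and
per-plate scale factors (log-normal), additive Gaussian kinetic read
noise, and additive Gaussian replicate noise on the effect scale.  The
default geometry mirrors a genome-scale 96-well arrayed screen: 12
control wells per plate (3 wells x 4 control roles), 84 test wells,
triplicate screening with up to 10 library plates per day, i.e. day
batches of up to 30 plates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from screensift.plate import rc_to_well

# fixed control-well positions (columns 11-12), identical on every plate
CONTROL_POSITIONS: dict[str, str] = {
    "A12": "neg_control",
    "B12": "neg_control",
    "C12": "neg_control",
    "D12": "pos_control",
    "E12": "pos_control",
    "F12": "pos_control",
    "G12": "tox_control_nt",
    "H12": "tox_control_nt",
    "A11": "tox_control_nt",
    "B11": "tox_control_casp3",
    "C11": "tox_control_casp3",
    "D11": "tox_control_casp3",
}

# normalized activity of each control role relative to the negative control:
# CASP3 knockdown suppresses the readout; the wild-type construct wells sit
# near baseline
CONTROL_EFFECTS = {
    "neg_control": 1.0,
    "pos_control": 0.4,
    "tox_control_nt": 0.12,
    "tox_control_casp3": 0.10,
}

TEST_WELLS: list[str] = [
    rc_to_well(r, c)
    for r in range(8)
    for c in range(12)
    if rc_to_well(r, c) not in CONTROL_POSITIONS
]

N_TEST_WELLS = len(TEST_WELLS)  # 84


class SimulationError(ValueError):
    pass


@dataclass
class ScreenTruth:
    """Ground truth of a simulated screen."""

    effects: dict[str, float]  # sirna_id -> multiplicative true effect (1 = null)
    spiked: list[str]  # siRNA ids with a planted suppressor effect
    position_factors: dict[str, dict[str, float]]  # batch_id -> well -> factor
    plate_scales: dict[str, float]  # plate_id -> scale factor
    noise_sd: float
    control_positions: dict[str, str] = field(default_factory=lambda: dict(CONTROL_POSITIONS))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def generate_screen(
    out_dir,
    n_sirna: int = 2000,
    n_spiked: int = 0,
    effect_range: tuple[float, float] = (0.4, 0.4),
    plates_per_day: int = 10,
    replicates: int = 3,
    noise_sd: float = 0.05,
    position_factor_sd: float = 0.15,
    plate_scale_sd: float = 0.05,
    base_activity: float = 2000.0,
    n_timepoints: int = 5,
    dt_min: float = 44.0,
    read_noise_rfu: float = 2.0,
    seed: int = 0,
) -> ScreenTruth:
    """Simulate a kinetic arrayed screen and write its four input files.

    Writes kinetics.csv, protein.csv, layout.csv, manifest.csv and
    truth.json into ``out_dir``.  Each library plate holds 84 test wells;
    plates are grouped into day batches of up to ``plates_per_day``
    library plates, each screened in ``replicates`` replicates (so a
    full day batch at the defaults is 30 plates).  Per-well activity is

        base_activity x plate_scale x position_factor x (effect + noise)

    with effect 1 for null siRNAs, a draw from ``effect_range`` for the
    ``n_spiked`` planted suppressors, and fixed role effects for control
    wells.  Kinetic reads are RFU(t) = 100 + slope*t + N(0, read noise)
    with slope = activity x protein mass.  Fully deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not (0 < effect_range[0] <= effect_range[1] < 1):
        raise SimulationError("effect_range must lie within (0, 1)")
    if n_spiked > n_sirna:
        raise SimulationError("n_spiked exceeds n_sirna")

    n_layout = -(-n_sirna // N_TEST_WELLS)  # ceil
    sirna_ids = [f"si{i:05d}" for i in range(n_sirna)]
    spiked = sorted(rng.choice(sirna_ids, size=n_spiked, replace=False).tolist())
    effects = {s: 1.0 for s in sirna_ids}
    for s in spiked:
        effects[s] = float(rng.uniform(*effect_range))

    # assign siRNAs to (layout plate, test well)
    placements: dict[str, dict[str, str]] = {}
    for i, s in enumerate(sirna_ids):
        lp, wi = divmod(i, N_TEST_WELLS)
        placements.setdefault(f"L{lp + 1:03d}", {})[TEST_WELLS[wi]] = s

    layout_ids = sorted(placements)
    batches: dict[str, list[str]] = {}
    for i, lp in enumerate(layout_ids):
        batches.setdefault(f"day{i // plates_per_day + 1}", []).append(lp)

    all_wells = sorted(CONTROL_POSITIONS) + TEST_WELLS
    position_factors = {
        b: {
            w: float(f)
            for w, f in zip(
                sorted(all_wells),
                np.exp(rng.normal(0.0, position_factor_sd, size=len(all_wells))),
            )
        }
        for b in sorted(batches)
    }

    kin_rows: list[str] = []
    prot_rows: list[str] = []
    layout_rows: list[str] = []
    manifest_rows: list[str] = []
    plate_scales: dict[str, float] = {}
    times = np.arange(n_timepoints) * dt_min

    for batch_id in sorted(batches):
        for lp in batches[batch_id]:
            for rep in range(1, replicates + 1):
                plate_id = f"{lp}r{rep}"
                scale = float(np.exp(rng.normal(0.0, plate_scale_sd)))
                plate_scales[plate_id] = scale
                manifest_rows.append(f"{plate_id},{batch_id},{rep}")
                # every plate carries the full 96-well grid; test wells
                # without an assigned siRNA are mock wells at the null effect
                for well in sorted(CONTROL_POSITIONS) + TEST_WELLS:
                    role = CONTROL_POSITIONS.get(well, "test")
                    sirna = placements[lp].get(well, "")
                    if role != "test":
                        effect = CONTROL_EFFECTS[role]
                    else:
                        effect = effects[sirna] if sirna else 1.0
                    noisy = effect + rng.normal(0.0, noise_sd)
                    activity = (
                        base_activity
                        * scale
                        * position_factors[batch_id][well]
                        * noisy
                    )
                    protein = float(np.exp(rng.normal(np.log(0.01), 0.1)))
                    slope = activity * protein
                    rfu = 100.0 + slope * times + rng.normal(
                        0.0, read_noise_rfu, size=times.size
                    )
                    layout_rows.append(f"{plate_id},{well},{role},{sirna}")
                    prot_rows.append(f"{plate_id},{well},{protein:.8g}")
                    for t, y in zip(times, rfu):
                        kin_rows.append(f"{plate_id},{well},{t:g},{y:.6f}")

    (out / "kinetics.csv").write_text(
        "plate_id,well,time_min,rfu\n" + "\n".join(kin_rows) + "\n"
    )
    (out / "protein.csv").write_text(
        "plate_id,well,protein_mg\n" + "\n".join(prot_rows) + "\n"
    )
    (out / "layout.csv").write_text(
        "plate_id,well,role,sirna_id\n" + "\n".join(layout_rows) + "\n"
    )
    (out / "manifest.csv").write_text(
        "plate_id,batch_id,replicate_index\n" + "\n".join(manifest_rows) + "\n"
    )
    truth = ScreenTruth(
        effects=effects,
        spiked=spiked,
        position_factors=position_factors,
        plate_scales=plate_scales,
        noise_sd=noise_sd,
    )
    truth.to_json(out / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# ontology + annotations
# ---------------------------------------------------------------------------

@dataclass
class OntologyTruth:
    """Ground truth of a simulated ontology/annotation set."""

    edges: list[tuple[str, str]]  # child is_a parent
    annotations: dict[str, list[str]]  # gene -> direct terms
    planted: list[str]  # enriched term ids
    planted_levels: dict[str, int]
    study: list[str]
    population: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _layer_sizes(n_terms: int, depth: int) -> list[int]:
    # geometric-ish growth from a single root down `depth` layers
    sizes = [1]
    remaining = n_terms - 1
    for d in range(1, depth + 1):
        take = max(1, round(remaining * (2**d) / sum(2**k for k in range(d, depth + 1))))
        take = min(take, remaining - (depth - d))
        sizes.append(max(1, take))
        remaining -= sizes[-1]
    sizes[-1] += remaining
    return sizes


def generate_ontology(
    out_dir,
    n_terms: int = 200,
    n_genes: int = 500,
    depth: int = 5,
    n_planted: int = 2,
    fold: float = 10.0,
    study_size: int = 100,
    background_rate: float = 0.05,
    namespace: str = "biological_process",
    seed: int = 0,
) -> OntologyTruth:
    """Simulate a layered is_a DAG with annotations and planted enrichment.

    Terms are arranged in ``depth`` layers below a single root; each term
    draws 1-2 parents from the layer above, so a term in layer d has
    level d.  Every gene receives direct annotations to random terms in
    layers >= 2 at rate ``background_rate`` per term (at least one
    term each).  ``n_planted`` terms in layers >= 3 are over-annotated in
    a designated study set by ``fold`` times the background rate,
    planting true enrichment below the near-root exclusion zone.

    Writes ontology.obo, annotations.gaf, study.txt, population.txt,
    library.txt (= population) and truth.json into ``out_dir``.
    """
    if depth < 3:
        raise SimulationError("depth must be >= 3 so planted terms sit below level 2")
    if n_planted > 0 and fold <= 1:
        raise SimulationError("fold must exceed 1 when planting enriched terms")
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sizes = _layer_sizes(n_terms, depth)
    layers: list[list[str]] = []
    counter = 1
    for d, size in enumerate(sizes):
        layer = [f"GO:{counter + i:07d}" for i in range(size)]
        counter += size
        layers.append(layer)
    root = layers[0][0]
    edges: list[tuple[str, str]] = []
    levels: dict[str, int] = {root: 0}
    for d in range(1, len(layers)):
        for term in layers[d]:
            n_par = int(rng.integers(1, min(2, len(layers[d - 1])) + 1))
            parents = rng.choice(layers[d - 1], size=n_par, replace=False)
            for p in sorted(parents.tolist()):
                edges.append((term, p))
            levels[term] = d

    genes = [f"g{i:04d}" for i in range(n_genes)]
    study = sorted(rng.choice(genes, size=study_size, replace=False).tolist())
    study_set = set(study)
    annotatable = [t for layer in layers[2:] for t in layer]
    annotations: dict[str, set[str]] = {g: set() for g in genes}
    for g in genes:
        mask = rng.random(len(annotatable)) < background_rate
        annotations[g].update(t for t, m in zip(annotatable, mask) if m)
        if not annotations[g]:
            annotations[g].add(annotatable[int(rng.integers(len(annotatable)))])

    deep = [t for layer in layers[3:] for t in layer]
    planted = sorted(
        rng.choice(deep, size=n_planted, replace=False).tolist()
    ) if n_planted else []
    study_rate = min(fold * background_rate, 0.95)
    for t in planted:
        for g in genes:
            rate = study_rate if g in study_set else background_rate
            if rng.random() < rate:
                annotations[g].add(t)

    # --- write OBO ---
    obo_lines = ["format-version: 1.2", f"ontology: synthetic-{seed}", ""]
    for layer in layers:
        for term in layer:
            obo_lines += [
                "[Term]",
                f"id: {term}",
                f"name: synthetic term {term[3:].lstrip('0') or '0'}",
                f"namespace: {namespace}",
            ]
            obo_lines += [
                f"is_a: {p} ! parent" for c, p in edges if c == term
            ]
            obo_lines.append("")
    (out / "ontology.obo").write_text("\n".join(obo_lines))

    # --- write GAF 2.1 ---
    gaf_lines = ["!gaf-version: 2.1"]
    for g in genes:
        for t in sorted(annotations[g]):
            gaf_lines.append(
                "\t".join(
                    [
                        "SYN", g, g, "", t, "SYN:0000001", "IEA", "",
                        "P", g, "", "protein", "taxon:9606",
                        "20200101", "SYN", "", "",
                    ]
                )
            )
    (out / "annotations.gaf").write_text("\n".join(gaf_lines) + "\n")
    (out / "study.txt").write_text("\n".join(study) + "\n")
    (out / "population.txt").write_text("\n".join(genes) + "\n")
    (out / "library.txt").write_text("\n".join(genes) + "\n")

    truth = OntologyTruth(
        edges=edges,
        annotations={g: sorted(ts) for g, ts in annotations.items()},
        planted=planted,
        planted_levels={t: levels[t] for t in planted},
        study=study,
        population=list(genes),
    )
    truth.to_json(out / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------

@dataclass
class InteractomeTruth:
    clique_seeds: list[str]
    bridge_pairs: list[tuple[str, str, str]]  # (seed_a, connector, seed_b)
    seeds: list[str]
    n_nodes: int
    n_edges: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def generate_interactome(
    out_dir,
    n_nodes: int = 200,
    n_edges: int = 500,
    n_seed_clique: int = 5,
    n_bridges: int = 4,
    indirect_fraction: float = 0.3,
    seed: int = 0,
) -> InteractomeTruth:
    """Simulate an interactome with a planted seed clique and bridges.

    A random (Erdős–Rényi G(n, m)) graph is decorated with a fully
    connected clique of ``n_seed_clique`` seed genes (direct relations)
    and ``n_bridges`` seed pairs joined only through one connector node
    (any direct seed-seed edge between those pairs is removed), so the
    direct network must recover exactly the clique and the
    shortest-path network (max 1 intervening) must recover the planted
    connectors.  Writes interactome.sif, seeds.txt and truth.json.
    """
    if n_seed_clique > n_nodes:
        raise SimulationError("clique larger than node count")
    if n_seed_clique + 3 * n_bridges > n_nodes:
        raise SimulationError("too many planted structures for node count")
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    names = [f"G{i:04d}" for i in range(n_nodes)]
    picked = rng.choice(names, size=n_seed_clique + 3 * n_bridges, replace=False)
    clique = sorted(picked[:n_seed_clique].tolist())
    bridge_nodes = picked[n_seed_clique:].tolist()

    edges: dict[frozenset, str] = {}

    def add(a, b, kind):
        if a != b:
            edges[frozenset((a, b))] = kind

    # random background
    target = n_edges
    while len(edges) < target:
        a, b = rng.choice(names, size=2, replace=False)
        kind = "indirect" if rng.random() < indirect_fraction else "direct"
        add(a, b, kind)

    # planted clique (direct)
    for i, a in enumerate(clique):
        for b in clique[i + 1 :]:
            add(a, b, "direct")

    # planted bridges: seed_a - connector - seed_b and no direct a-b edge
    bridge_pairs = []
    protected: set[frozenset] = {
        frozenset((a, b)) for i, a in enumerate(clique) for b in clique[i + 1 :]
    }
    for i in range(n_bridges):
        a, x, b = bridge_nodes[3 * i : 3 * i + 3]
        a, b = sorted((a, b))
        add(a, x, "direct")
        add(x, b, "direct")
        protected |= {frozenset((a, x)), frozenset((x, b))}
        bridge_pairs.append((a, x, b))

    seeds = sorted(clique + [p[0] for p in bridge_pairs] + [p[2] for p in bridge_pairs])
    seed_set = set(seeds)
    # the direct network must recover exactly the clique: strip background
    # seed-seed edges outside it
    for key in list(edges):
        if set(key) <= seed_set and key not in protected:
            del edges[key]
    # each planted connector must be the unique 1-hop bridge for its pair
    for a, x, b in bridge_pairs:
        for n in names:
            if n == x:
                continue
            ka, kb = frozenset((a, n)), frozenset((n, b))
            if ka in edges and kb in edges:
                del edges[kb if kb not in protected else ka]
    sif_lines = []
    for key in sorted(edges, key=lambda k: tuple(sorted(k))):
        a, b = sorted(key)
        sif_lines.append(f"{a}\t{edges[key]}\t{b}")
    (out / "interactome.sif").write_text("\n".join(sif_lines) + "\n")
    (out / "seeds.txt").write_text("\n".join(seeds) + "\n")
    truth = InteractomeTruth(
        clique_seeds=clique,
        bridge_pairs=bridge_pairs,
        seeds=seeds,
        n_nodes=n_nodes,
        n_edges=len(edges),
    )
    truth.to_json(out / "truth.json")
    return truth
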