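import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from screensift import plate, simulate as sim  # noqa: E402


@pytest.fixture(scope="session")
def small_screen(tmp_path_factory):
    """A small simulated screen (200 siRNAs, 10 spiked) with its truth."""
    out = tmp_path_factory.mktemp("screen")
    truth = sim.generate_screen(
        out, n_sirna=200, n_spiked=10, effect_range=(0.4, 0.4), noise_sd=0.05, seed=101
    )
    return out, truth


@pytest.fixture(scope="session")
def small_screen_activities(small_screen):
    out, truth = small_screen
    reads = plate.read_kinetic_csv(out / "kinetics.csv")
    protein = plate.read_protein_csv(out / "protein.csv")
    layouts = plate.read_layout_csv(out / "layout.csv")
    acts = plate.quantify_plates(reads, protein, layouts)
    manifest = pd.read_csv(out / "manifest.csv", dtype={"plate_id": str})
    return acts, manifest, truth


@pytest.fixture(scope="session")
def small_ontology(tmp_path_factory):
    """A synthetic ontology with two planted enriched terms."""
    out = tmp_path_factory.mktemp("onto")
    truth = sim.generate_ontology(out, seed=11)
    return out, truth


def write_obo(path, terms, edges, namespace="biological_process", alt_ids=(),
              obsolete=()):
    """Write a minimal OBO 1.2 file for parser tests.

    ``alt_ids`` is an iterable of (canonical, alt) pairs, ``obsolete`` a
    set of term ids marked is_obsolete.
    """
    lines = ["format-version: 1.2", ""]
    alt_map = {}
    for canon, alt in alt_ids:
        alt_map.setdefault(canon, []).append(alt)
    for t in terms:
        lines += [
            "[Term]", f"id: {t}", f"name: name of {t}", f"namespace: {namespace}"
        ]
        lines += [f"alt_id: {a}" for a in alt_map.get(t, [])]
        lines += [f"is_a: {p}" for c, p in edges if c == t]
        if t in obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    Path(path).write_text("\n".join(lines))
    return path
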