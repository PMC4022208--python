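import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tyscape.align import AlignmentParams
from tyscape.classify import classify_strain
from tyscape.scan import QueryPanel, scan_ltrs
from tyscape.synthetic import (
    CategoryCounts,
    PlantSpec,
    build_templates,
    simulate_strain_panel,
)

TEMPLATE_SEED = 7


@pytest.fixture(scope="session")
def templates():
    return build_templates(TEMPLATE_SEED)


@pytest.fixture(scope="session")
def panel(templates):
    return QueryPanel.from_templates(templates)


@pytest.fixture(scope="session")
def params():
    return AlignmentParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_panel(templates):
    """3 strains x 250 kb with mixed categories (no hybrids), divergence 0."""
    spec = PlantSpec(
        seed=31,
        genome_length=250_000,
        n_strains=3,
        counts={
            "Ty1": CategoryCounts(full=2, solo_ltr=7, relic=1),
            "Ty2": CategoryCounts(full=1, solo_ltr=3),
            "Ty3": CategoryCounts(full=1, solo_ltr=2),
            "Ty4": CategoryCounts(solo_ltr=1),
            "Ty5": CategoryCounts(solo_ltr=1),
        },
    )
    return simulate_strain_panel(spec, templates=templates)


@pytest.fixture(scope="session")
def small_panel_detected(small_panel, panel, params):
    """Stage 1+2 results for every strain of the small panel."""
    hits = {}
    elements = {}
    for strain, asm in small_panel.strains.items():
        hits[strain] = scan_ltrs(asm, panel, params)
        elements[strain] = classify_strain(hits[strain], asm, panel, params)
    return hits, elements
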