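"""Packaged fixtures.

``table1_wky_vs_shr.csv`` and ``table2_shr_vs_shrh.csv`` transcribe the
published serum biomarker tables for the disease contrast (SHR-N vs WKY-N)
and the treatment contrast (SHR-H vs SHR-N): metabolite name, chemical
shifts with multiplicity codes, t-test p, VIP and fold change.

``resonances.csv`` is the resonance library used by the spectrum simulator:
one row per resonance with equal relative areas within a metabolite and a
baseline serum concentration (arbitrary units) chosen to give realistic
relative peak sizes.

``pathways_synthetic/`` holds small hand-curated reaction-adjacency graphs
standing in for the corresponding KEGG pathway maps (synthetic: the node
sets and edges are reduced sketches, not database exports), plus decoy
pathways that share no biomarkers. ``protein_map_synthetic.csv`` is a
curated metabolite-to-protein association list over the ten
hypertension-related enzymes discussed with the biomarker set; it too is a
synthetic stand-in for the published network figure.
"""

from importlib import resources
from pathlib import Path

RESONANCES = "resonances.csv"
TABLE1 = "table1_wky_vs_shr.csv"
TABLE2 = "table2_shr_vs_shrh.csv"
PROTEIN_MAP = "protein_map_synthetic.csv"
PATHWAY_INDEX = "pathways_synthetic/index.csv"


def fixture_path(name: str) -> Path:
    """Return the filesystem path of a packaged fixture file."""
    return Path(resources.files(__package__).joinpath(name))
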