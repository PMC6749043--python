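"""Canonical metabolite naming shared across modules.

The source tables mix capitalization ("Alanine" vs "alanine") and list the
lipoprotein signal as both LDL/VLDL and VLDL/LDL; set operations and
effect-table lookups therefore go through one case-insensitive alias map.
"""

from __future__ import annotations

import re

#: alias map applied after casefolding; keys are variants, values canonical
NAME_ALIASES = {
    "vldl/ldl": "ldl/vldl",
    "n, n-dimethylglycine": "n,n-dimethylglycine",
}


def normalize_name(name: str) -> str:
    """Case-insensitive canonical metabolite name for set operations."""
    key = re.sub(r"\s+", " ", name.strip()).casefold()
    return NAME_ALIASES.get(key, key)
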