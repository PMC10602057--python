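"""Packaged region lists: the Desikan-Killiany universe and the published
genetically informed brain network (GIBN) memberships.

The universe is the 34 bilateral cortical regions of the Desikan-Killiany
gyral-anatomy atlas (FreeSurfer short names).  The network memberships are
the region sets reported for the six surface-area networks (SA1-SA6) and
four cortical-thickness networks (CT1-CT4) discovered from the ENIGMA-3
cortical GWAS; they serve as fixtures for the overlap statistics and as
in-package reference inputs.
"""

from __future__ import annotations

import json
from importlib import resources

from gibnet.overlap import RegionSet

__all__ = ["desikan_killiany_34", "reference_networks"]


def desikan_killiany_34() -> list[str]:
    """The 34 Desikan-Killiany cortical region names (bilateral averages)."""
    text = resources.files("gibnet.data").joinpath("desikan_killiany_34.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def reference_networks() -> dict[str, RegionSet]:
    """Published GIBN region sets (SA1-SA6, CT1-CT4) validated against the universe."""
    universe = desikan_killiany_34()
    raw = json.loads(resources.files("gibnet.data").joinpath("gibn_regions.json").read_text())
    return {
        name: RegionSet.from_labels(name, labels, universe) for name, labels in raw.items()
    }
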