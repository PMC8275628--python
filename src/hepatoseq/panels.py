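"""Bundled marker panels (YAML) and their loaders.

Panels ship with the package but any user-supplied YAML file with the same
structure can be passed to the loaders instead.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from hepatoseq.zonation import ZonationMarkerPanel

_PANEL_DIR = resources.files("hepatoseq") / "data"


def _load_yaml(name_or_path: str | Path, bundled: str) -> dict:
    path = Path(name_or_path) if name_or_path else None
    if path is not None and path.exists():
        text = path.read_text()
    else:
        text = (_PANEL_DIR / bundled).read_text()
    return yaml.safe_load(text)


def load_celltype_panel(path: str | Path | None = None) -> dict[str, list[str]]:
    """Cell-type label -> marker genes mapping for cluster annotation."""
    return _load_yaml(path or "", "celltype_markers.yaml")


def load_zonation_panel(path: str | Path | None = None) -> ZonationMarkerPanel:
    """Pericentral / periportal / non-zonated marker lists."""
    raw = _load_yaml(path or "", "zonation_markers.yaml")
    return ZonationMarkerPanel(
        pericentral=list(raw["pericentral"]),
        periportal=list(raw["periportal"]),
        non_zonated=list(raw.get("non_zonated", [])),
    )


def load_stem_panel(path: str | Path | None = None) -> list[str]:
    """Stem/progenitor marker list for binary co-expression analysis."""
    raw = _load_yaml(path or "", "stem_markers.yaml")
    return list(raw["stem_markers"])
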