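"""Packaged datasets: assay geometries and the published mutation catalogs.

The catalogs transcribe the source study's printed tables:

* ``thf_bypass`` — 394 sequenced bypass products of a site-specific abasic
  (THF) lesion on a plasmid; lesion-site insertions (243 A / 80 C / 71 T)
  and 23 flanking mutations (5 upstream, 18 downstream).
* ``thf_control`` — 456 products of the matched lesion-free control
  plasmid; 17 mutations (6 upstream, 11 downstream).
* ``thf_msh2`` — 47 bypass products from mismatch-repair-deficient cells,
  220-nt downstream region sequenced, zero mutations found.
* ``uv_revertants`` — 165 UV-induced reversion products of a chromosomal
  TC-dipyrimidine lesion; 17 flanking mutations (2 upstream, 15
  downstream).  Per-product lesion-site codon changes are printed only for
  those 17; the remaining outcomes are synthetic placeholders constructed
  to reproduce the published aggregate (exactly 12 of 165 products carry a
  co-mutation at the adjacent +1 G).
* ``uv_canr`` — 161 lesion-independent control mutants from the same
  irradiated populations; 3 mutations, 1 within the downstream kilobase.
* ``uv_rad30`` — 165 revertants lacking the alternative TLS polymerase;
  5 downstream mutations reported only as lying between 505 and 1026 nt,
  so the interior fixture positions are synthetic (endpoints preserved).
* ``uv_rev3`` — 231 revertants lacking the extension polymerase; zero
  downstream mutations.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .catalog import AffineBranch, AssayGeometry, Catalog, CoordMap, load_catalog

__all__ = [
    "geometry_registry",
    "load_fixture",
    "load_thf_bypass",
    "load_thf_control",
    "load_thf_msh2",
    "load_uv_revertants",
    "load_uv_canr",
    "load_uv_rad30",
    "load_uv_rev3",
    "FIXTURE_FILES",
]

FIXTURE_FILES = {
    "thf_bypass": "thf_bypass.tsv",
    "thf_control": "thf_control.tsv",
    "thf_msh2": "thf_msh2.tsv",
    "uv_revertants": "uv_revertants.tsv",
    "uv_canr": "uv_canr.tsv",
    "uv_rad30": "uv_rad30_synthetic_positions.tsv",
    "uv_rev3": "uv_rev3.tsv",
}


def _data_path(name: str):
    return resources.files("tlstracts").joinpath("data", name)


def geometry_registry(path=None) -> dict[str, AssayGeometry]:
    """Load the assay-geometry registry (packaged default or a YAML path)."""
    if path is None:
        text = _data_path("geometries.yaml").read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    registry: dict[str, AssayGeometry] = {}
    for assay_id, spec in raw.items():
        maps = {}
        for name, branches in (spec.get("coord_maps") or {}).items():
            maps[name] = CoordMap(name, tuple(
                AffineBranch(
                    d_min=b["d_min"], d_max=b["d_max"], slope=b["slope"],
                    offset=b["offset"], system=b["system"],
                    suffix=b.get("suffix", ""),
                )
                for b in branches
            ))
        registry[assay_id] = AssayGeometry(
            assay_id=assay_id,
            lesion_label=spec["lesion_label"],
            upstream_extent=spec["upstream_extent"],
            downstream_extent=spec["downstream_extent"],
            excluded_intervals=tuple(tuple(iv) for iv in spec.get("excluded_intervals", [])),
            coord_maps=maps,
        )
    return registry


@lru_cache(maxsize=None)
def _cached_fixture(name: str) -> Catalog:
    with resources.as_file(_data_path(FIXTURE_FILES[name])) as path:
        return load_catalog(path, geometry_registry())


def load_fixture(name: str) -> Catalog:
    """Load a packaged catalog by short name (see FIXTURE_FILES)."""
    if name not in FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURE_FILES)}")
    return _cached_fixture(name)


def load_thf_bypass() -> Catalog:
    return load_fixture("thf_bypass")


def load_thf_control() -> Catalog:
    return load_fixture("thf_control")


def load_thf_msh2() -> Catalog:
    return load_fixture("thf_msh2")


def load_uv_revertants() -> Catalog:
    return load_fixture("uv_revertants")


def load_uv_canr() -> Catalog:
    return load_fixture("uv_canr")


def load_uv_rad30() -> Catalog:
    return load_fixture("uv_rad30")


def load_uv_rev3() -> Catalog:
    return load_fixture("uv_rev3")
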