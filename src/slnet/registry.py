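"""ROI registry: region names, hemispheres, lobe blocks, cerebellum flags.

The bundled default registry encodes the 116-region AAL parcellation
(54 regions per hemisphere plus 8 midline vermis structures, 26 of the
116 cerebellar).  The lobe-block grouping (frontal, temporal-L/R,
parieto-occipital including precuneus/cuneus/lingual, subcortical,
cerebellar including the vermis) is a documented approximation used for
block-level summaries.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "load_registry", "make_registry",
           "exclude_cerebellum"]

REQUIRED_COLUMNS = ("region", "hemisphere", "block", "cerebellum")


def _validate(reg: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in reg.columns]
    if missing:
        raise ValueError(f"registry missing required columns: {missing}")
    dup = reg["region"][reg["region"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate region names in registry: {sorted(set(dup))}")
    bad = set(reg["hemisphere"]) - {"L", "R", "midline"}
    if bad:
        raise ValueError(f"invalid hemisphere values: {sorted(bad)}")
    reg = reg.copy()
    reg["cerebellum"] = reg["cerebellum"].astype(int)
    return reg.reset_index(drop=True)


def load_registry(path=None) -> pd.DataFrame:
    """Load and validate a ROI registry TSV.

    With no path, the bundled 116-region AAL registry is returned.
    """
    if path is None:
        source = resources.files("slnet.data").joinpath("aal116.tsv")
        with resources.as_file(source) as p:
            reg = pd.read_csv(p, sep="\t")
    else:
        reg = pd.read_csv(path, sep="\t")
    return _validate(reg)


def make_registry(block_map, region_labels=None) -> pd.DataFrame:
    """Build a synthetic registry from a block map (testing/demo helper).

    Hemispheres alternate L/R within each block; regions of the
    'cerebellar' block are flagged cerebellar.
    """
    if region_labels is None:
        region_labels = [f"{b}_{k:03d}" for k, b in enumerate(block_map)]
    rows = []
    for k, (label, block) in enumerate(zip(region_labels, block_map)):
        rows.append({"region": label,
                     "hemisphere": "L" if k % 2 == 0 else "R",
                     "block": block,
                     "cerebellum": int(block == "cerebellar")})
    return _validate(pd.DataFrame(rows))


def exclude_cerebellum(registry: pd.DataFrame, subjects):
    """Drop cerebellar regions consistently from the registry and from
    every subject's time-series matrix (row order otherwise preserved).

    Returns ``(filtered_registry, filtered_subjects)``.
    """
    from dataclasses import replace

    reg = _validate(registry)
    keep = ~reg["cerebellum"].astype(bool)
    filtered_reg = reg[keep].reset_index(drop=True)
    keep_mask = keep.to_numpy()
    kept_labels = tuple(filtered_reg["region"])
    out = []
    for s in subjects:
        if s.values.shape[0] != len(reg):
            raise ValueError(
                f"subject {s.subject_id} has {s.values.shape[0]} rows, "
                f"registry has {len(reg)}")
        if s.region_labels is not None and tuple(s.region_labels) != tuple(reg["region"]):
            raise ValueError(
                f"subject {s.subject_id} region labels do not match registry")
        out.append(replace(s, values=s.values[keep_mask],
                           region_labels=kept_labels))
    return filtered_reg, out
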