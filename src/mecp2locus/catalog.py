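"""Loaders for the packaged fragment catalogue and expectation fixtures."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .coloc import FragmentSet
from .coordinates import RelativeInterval
from .locus import CisRegulatoryElement


def _read_tsv(name: str) -> pd.DataFrame:
    path = resources.files("mecp2locus.data").joinpath(name)
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_segment_catalog() -> dict[str, FragmentSet]:
    """The S/A/B/H consensus-segment catalogue as TSS-relative fragment sets."""
    df = _read_tsv("segment_catalog.tsv")
    out: dict[str, FragmentSet] = {}
    for set_name, group in df.groupby("set", sort=False):
        intervals = [
            RelativeInterval(row.start_kb, row.end_kb, row.label, row.assembly)
            for row in group.itertuples()
        ]
        out[set_name] = FragmentSet.from_relative_intervals(set_name, intervals)
    return out


def load_cis_re_fixture() -> tuple[FragmentSet, list[CisRegulatoryElement]]:
    """Synthetic cis-RE placements as a fragment set plus typed elements.

    The genomic positions of the F elements are not published as plain
    coordinates; these are synthetic stand-ins consistent with the
    catalogued containment relations (see the fixture header).
    """
    df = _read_tsv("cis_re_fixture.tsv")
    intervals = [
        RelativeInterval(row.start_kb, row.end_kb, row.name, row.assembly)
        for row in df.itertuples(index=False)
    ]
    fragment_set = FragmentSet.from_relative_intervals("cisRE", intervals)
    elements = [
        CisRegulatoryElement(
            name=row.name,
            role=row.role,
            interval=(int(round(row.start_kb * 1000)), int(round(row.end_kb * 1000))),
        )
        for row in df.itertuples(index=False)
    ]
    return fragment_set, elements


def load_expected_domain_table(which: str) -> pd.DataFrame:
    """Expectation matrix for the synthetic panel ('ncbi' or 'uniprot')."""
    if which not in {"ncbi", "uniprot"}:
        raise ValueError("which must be 'ncbi' or 'uniprot'")
    df = _read_tsv(f"expected_domain_table_{which}.tsv")
    return df.set_index("row").rename_axis(None)
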