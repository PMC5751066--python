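"""Packaged study fixtures: the 24-row comparative-mapping table and summary counts.

The comparative-mapping fixture records, per Japanese yellowtail RH group,
the number of yellowtail markers that mapped to greater amberjack scaffolds,
the homologous medaka chromosome, and the number of amberjack transcripts
that mapped to that medaka chromosome.  The 24 RH-group <-> chromosome pairs
form the fixed 1-to-1 homology backbone of the anchoring pipeline.

``REPORTED`` carries the study's printed summary totals so consistency
checks (column sums vs printed totals, placement percentages, DE partition
totals) can be recomputed rather than asserted.  Note one internal
discrepancy in the source tables, preserved deliberately: the per-group
marker counts sum to 467 while the running text reports 468 mapped markers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "comparative_map_table",
    "homology_pairs",
    "sex_gene_placements",
    "REPORTED",
]

#: Printed summary totals from the greater amberjack genome study.
REPORTED: dict[str, int] = {
    "markers_mapped": 468,  # running text; the per-group column sums to 467
    "marker_bearing_scaffolds": 409,
    "scaffolds_mapped_to_reference": 14990,
    "transcripts_total": 53023,
    "transcripts_on_groups": 44371,
    "transcripts_on_reference": 30342,
    "gonad_de_total": 7199,
    "gonad_de_female_biased": 2522,
    "gonad_de_male_biased": 4677,
    "gonad_de_assigned_to_groups": 4266,
    "muscle_up_in_slow": 40,
    "muscle_up_in_fast": 52,
}


def _data_path(name: str):
    return resources.files("synanchor.data").joinpath(name)


def comparative_map_table() -> pd.DataFrame:
    """The 24-row per-group marker/transcript mapping table.

    Columns: rh_group, n_markers, ref_chromosome, n_transcripts.
    """
    with resources.as_file(_data_path("comparative_map.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def homology_pairs() -> list[tuple[str, str]]:
    """The 24 (rh_group, reference_chromosome) 1-to-1 pairs, in table order."""
    df = comparative_map_table()
    return list(zip(df["rh_group"], df["ref_chromosome"]))


def sex_gene_placements() -> pd.DataFrame:
    """Known teleost sex-determining genes located on the in silico groups.

    Columns: gene, abbreviation, in_silico_group, de_gonad ("up_in_male",
    "up_in_female", "no_expression", or NA when the gene was not found).
    """
    with resources.as_file(_data_path("sex_gene_placements.tsv")) as p:
        return pd.read_csv(p, sep="\t")
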