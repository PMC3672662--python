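"""Packaged reference data.

The limiting-dilution transplantation tables of basal stem/progenitor
cells from parous and age-matched virgin donors are transcribed from the
published dose-response counts.  Outgrowths were scored at three
stringencies: variant ``c`` counts outgrowths filling >= 25% of the fat
pad, variant ``d`` those filling >= 10%, and variant ``e`` also includes
rudimentary outgrowths (>= 3% filled).

The Wnt/Notch gene sets here are illustrative stand-ins assembled from
genes commonly discussed for these pathways in mammary epithelium; they
are synthetic conveniences for demos and tests, not an authoritative
pathway annotation.
"""

from __future__ import annotations

from .gsea import GeneSetCollection
from .limiting_dilution import DilutionAssay

__all__ = ["transplant_doses", "load_transplant_tables", "illustrative_gene_sets"]

_DOSES = (1000.0, 500.0, 250.0, 100.0, 50.0)
_N_INJECTED = (9, 11, 6, 6, 7)

# positives per dose group, keyed by (donor, scoring variant)
_POSITIVES = {
    ("virgin", "c"): (8, 8, 2, 0, 0),
    ("virgin", "d"): (8, 8, 2, 1, 0),
    ("virgin", "e"): (8, 8, 2, 1, 0),
    ("parous", "c"): (3, 2, 0, 0, 1),
    ("parous", "d"): (3, 2, 1, 0, 1),
    ("parous", "e"): (4, 6, 1, 2, 1),
}


def transplant_doses() -> tuple[tuple[float, ...], tuple[int, ...]]:
    """The dose ladder (cells/injection) and injections per dose."""
    return _DOSES, _N_INJECTED


def load_transplant_tables() -> dict[str, DilutionAssay]:
    """All six published dose-response tables, keyed ``donor_variant``.

    Note the virgin tables for variants d and e coincide (the extra
    rudimentary outgrowths after parity all fell below the 10% size).
    """
    return {
        f"{donor}_{variant}": DilutionAssay(
            doses=_DOSES,
            n_injected=_N_INJECTED,
            n_positive=pos,
            group_label=f"{donor}_{variant}",
        )
        for (donor, variant), pos in _POSITIVES.items()
    }


def illustrative_gene_sets() -> GeneSetCollection:
    """Small synthetic Wnt-target / Notch gene sets for demos and tests."""
    return GeneSetCollection(
        sets={
            "WNT_TARGETS_ILLUSTRATIVE": frozenset(
                ["Lgr5", "Axin2", "Vcan", "Igfbp3", "Krt15", "Cd44", "Fst", "Myc"]
            ),
            "NOTCH_PATHWAY_ILLUSTRATIVE": frozenset(
                ["Jag2", "Gata3", "Id3", "Dusp1", "Maml2", "Hey1", "Hes1", "Notch1"]
            ),
        },
        descriptions={
            "WNT_TARGETS_ILLUSTRATIVE": "synthetic demo set of canonical Wnt targets",
            "NOTCH_PATHWAY_ILLUSTRATIVE": "synthetic demo set of Notch pathway members",
        },
    )
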