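"""Sample selection and probe quality control for donor microarray bundles.

The atlas-style bundles arrive with thousands of samples spread over both
hemispheres and all tissue classes, and with probes whose sequence-level
reannotation status varies.  This module applies the selection rules used
throughout the analysis:

* samples: left hemisphere, slab type "cortex", within 3 mm of a cortical
  region of interest, and not annotated with a non-cortical structure label;
* probes: uniquely mapped to a single gene (multi-gene, intergenic and
  unmapped probes are excluded), and flagged "expressed" in at least 300 of
  the retained cortical samples.

All operations are pure predicates over pandas tables: order-preserving,
idempotent, and conserving counts (retained + excluded = input).
"""

from __future__ import annotations

from typing import AbstractSet, Iterable, Mapping

import pandas as pd

__all__ = [
    "MAPPING_STATUSES",
    "select_cortical_samples",
    "classify_probes",
    "count_expressed_samples",
    "filter_low_expression",
    "write_filter_report",
]

#: Recognised probe reannotation outcomes.
MAPPING_STATUSES = ("unique", "multi_gene", "intergenic", "unmapped")

#: Sample table columns used by :func:`select_cortical_samples`.
SAMPLE_COLUMNS = (
    "sample_id",
    "donor_id",
    "mni_x",
    "mni_y",
    "mni_z",
    "slab_type",
    "structure_label",
    "hemisphere",
    "dist_to_cortex_roi",
)


def select_cortical_samples(
    samples: pd.DataFrame,
    max_dist: float = 3.0,
    noncortical_labels: AbstractSet[str] = frozenset(),
) -> pd.DataFrame:
    """Retain left-hemisphere cortical samples near a cortical region of interest.

    A sample is retained iff hemisphere == "left", slab_type == "cortex",
    dist_to_cortex_roi <= max_dist (inclusive) and its structure label is not
    in ``noncortical_labels``.  Row order is preserved; the result may be
    empty.
    """
    keep = (
        (samples["hemisphere"] == "left")
        & (samples["slab_type"] == "cortex")
        & (samples["dist_to_cortex_roi"] <= max_dist)
        & ~samples["structure_label"].isin(noncortical_labels)
    )
    return samples.loc[keep]


def classify_probes(probes: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition probes by reannotation outcome; only uniquely mapped survive.

    Returns a dict with keys ``retained`` (status "unique"),
    ``excluded_multi``, ``excluded_intergenic`` and ``excluded_unmapped``.
    Partition sizes sum to the input size.

    Raises
    ------
    ValueError
        If any probe carries an unrecognised mapping status.
    """
    status = probes["mapping_status"]
    unknown = set(status.unique()) - set(MAPPING_STATUSES)
    if unknown:
        raise ValueError(f"unknown mapping status values: {sorted(unknown)}")
    return {
        "retained": probes.loc[status == "unique"],
        "excluded_multi": probes.loc[status == "multi_gene"],
        "excluded_intergenic": probes.loc[status == "intergenic"],
        "excluded_unmapped": probes.loc[status == "unmapped"],
    }


def count_expressed_samples(expressed: pd.DataFrame) -> pd.Series:
    """Number of samples in which each probe is flagged expressed.

    ``expressed`` is a probes x samples boolean table (the binary
    presence/absence calls shipped with the expression bundle); counting is
    done over whatever samples the caller retained, so apply sample selection
    first.
    """
    return expressed.sum(axis=1).astype(int)


def filter_low_expression(probes: pd.DataFrame, min_samples: int = 300) -> pd.DataFrame:
    """Drop probes expressed in strictly fewer than ``min_samples`` samples.

    A probe with exactly ``min_samples`` expressed samples is retained.
    Requires an ``n_expressed_samples`` column.
    """
    return probes.loc[probes["n_expressed_samples"] >= min_samples]


def write_filter_report(path, counts: Mapping[str, int] | Iterable[tuple[str, int]]) -> None:
    """Write per-category probe/sample counts as a two-column TSV."""
    items = counts.items() if isinstance(counts, Mapping) else counts
    pd.DataFrame(items, columns=["category", "count"]).to_csv(path, sep="\t", index=False)
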