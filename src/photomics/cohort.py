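"""Core in-memory containers for paired UV-exposure cohorts.

The study design is a within-subject contrast: every subject contributes one
control and one irradiated epidermal sample, profiled on two molecular levels
(gene expression as TPM, CpG methylation as Beta values). Subject-level
phenotypes carry the minimal erythema dose (MED, mJ/cm^2) and the Fitzpatrick
phototype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
IRRADIATED = "irradiated"
CONDITIONS = (CONTROL, IRRADIATED)

REGION_CLASSES = ("TSS200", "TSS1500", "Exon", "Enhancer", "Intergenic")
ISLAND_RELATIONS = ("OpenSea", "Shelf", "Shore", "Island")


class CohortValidationError(ValueError):
    """Raised when a cohort violates the paired-design invariants."""


@dataclass
class PairedOmicsCohort:
    """Paired expression + methylation matrices with sample/subject metadata.

    Parameters
    ----------
    expression
        gene x sample matrix on TPM scale (non-negative).
    methylation_beta
        CpG x sample matrix of Beta values, strictly inside (0, 1).
    sample_table
        indexed by sample id; columns ``subject`` and ``condition``
        (``control`` or ``irradiated``).
    subject_table
        indexed by subject id; columns ``med`` (mJ/cm^2), ``fitzpatrick``
        and, for synthetic cohorts, ``true_subtype``.
    """

    expression: pd.DataFrame
    methylation_beta: pd.DataFrame
    sample_table: pd.DataFrame
    subject_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        samples = list(self.sample_table.index)
        for name, mat in (("expression", self.expression),
                          ("methylation_beta", self.methylation_beta)):
            if list(mat.columns) != samples:
                missing = set(samples) - set(mat.columns)
                raise CohortValidationError(
                    f"{name} columns do not match sample table"
                    + (f"; missing sample(s): {sorted(missing)}" if missing else "")
                )
            if not mat.index.is_unique:
                raise CohortValidationError(f"{name} row ids are not unique")
        if (self.expression.to_numpy() < 0).any():
            raise CohortValidationError("expression contains negative TPM values")
        beta = self.methylation_beta.to_numpy()
        if (beta <= 0).any() or (beta >= 1).any():
            raise CohortValidationError("Beta values must lie strictly inside (0, 1)")
        bad = set(self.sample_table["condition"]) - set(CONDITIONS)
        if bad:
            raise CohortValidationError(f"unknown condition label(s): {sorted(bad)}")
        # exactly one sample per subject per condition
        counts = self.sample_table.groupby(["subject", "condition"]).size()
        for subject in self.sample_table["subject"].unique():
            for cond in CONDITIONS:
                if counts.get((subject, cond), 0) != 1:
                    raise CohortValidationError(
                        f"subject {subject!r} does not have exactly one "
                        f"{cond} sample"
                    )
        missing_subj = set(self.sample_table["subject"]) - set(self.subject_table.index)
        if missing_subj:
            raise CohortValidationError(
                f"sample table references unknown subject(s): {sorted(missing_subj)}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def subjects(self) -> list:
        return list(self.subject_table.index)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_table)

    def samples_for(self, condition: str) -> pd.Series:
        """Map subject -> sample id for one condition (subject-table order)."""
        sub = self.sample_table[self.sample_table["condition"] == condition]
        mapping = pd.Series(sub.index.values, index=sub["subject"].values)
        return mapping.reindex(self.subjects)

    def med_per_sample(self) -> pd.Series:
        """MED target repeated for both samples of each subject."""
        med = self.subject_table["med"]
        return pd.Series(
            med.reindex(self.sample_table["subject"]).to_numpy(),
            index=self.sample_table.index,
            name="med",
        )

    def expression_log2(self) -> pd.DataFrame:
        """log2(TPM + 1), the scale all downstream statistics use."""
        return np.log2(self.expression + 1.0)


@dataclass
class CpGManifest:
    """Per-CpG genomic annotation: coordinates, gene links, island relation.

    ``sites`` is indexed by CpG id with columns ``chromosome``, ``position``
    (1-based) and ``island_relation``; ``links`` is a long table with columns
    ``cpg_id``, ``gene_id``, ``region_class`` (0-2 rows per CpG).
    """

    sites: pd.DataFrame
    links: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cpg_id", "gene_id", "region_class"]))

    def __post_init__(self) -> None:
        if not self.sites.index.is_unique:
            dups = self.sites.index[self.sites.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated cpg_id(s) in manifest: {dups}")
        if (self.sites["position"] < 1).any():
            raise ValueError("manifest positions must be >= 1 (1-based)")
        bad = set(self.sites["island_relation"]) - set(ISLAND_RELATIONS)
        if bad:
            raise ValueError(f"unknown island relation token(s): {sorted(bad)}")
        if len(self.links):
            bad = set(self.links["region_class"]) - set(REGION_CLASSES)
            if bad:
                raise ValueError(f"unknown region class token(s): {sorted(bad)}")
            unknown = set(self.links["cpg_id"]) - set(self.sites.index)
            if unknown:
                raise ValueError(
                    f"links reference CpGs absent from manifest: {sorted(unknown)[:5]}"
                )

    @property
    def cpg_ids(self) -> pd.Index:
        return self.sites.index

    def links_for_gene(self, gene_id: str) -> pd.DataFrame:
        return self.links[self.links["gene_id"] == gene_id]


@dataclass(frozen=True)
class GenomicBlock:
    """Reference genomic interval with a reported methylation change.

    Coordinates are 0-based half-open (BED convention); manifest positions
    are 1-based, so a CpG falls inside iff ``start < position <= end``.
    """

    block_id: str
    chromosome: str
    start: int
    end: int
    reference_delta: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"block {self.block_id}: start must be < end "
                f"(got {self.start}, {self.end})"
            )

    def contains(self, chromosome: str, position: int) -> bool:
        return chromosome == self.chromosome and self.start < position <= self.end
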