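"""Reading and writing genotype tables and result files.

The native input format is the MDR-style flat file: tab-delimited, one
header row, one subject per row, genotype columns coded 0/1/2 followed by a
binary class column (1 = case). CSV with the same schema is accepted.
Result files are plain TSV, written with 6 significant digits so they
round-trip losslessly at that precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset, InteractionResult, RiskScoreProfile

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "write_interaction_results",
    "read_interaction_results",
    "write_risk_scores",
    "read_risk_scores",
]

log = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "NA", "NaN", "?", "."}
_FLOAT_FMT = "%.6g"


def _sep(dialect: str) -> str:
    if dialect == "mdr-flat":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r}; use 'mdr-flat' or 'csv'")


def read_genotype_table(
    path: str | Path,
    dialect: str = "mdr-flat",
    class_column: str = "Class",
    missing: str = "fail",
    recode: dict[str, int] | None = None,
) -> GenotypeDataset:
    """Load a genotype table into a validated :class:`GenotypeDataset`.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"mdr-flat"`` (tab-delimited, default) or ``"csv"``.
    class_column
        Name of the binary phenotype column (default ``"Class"``).
    missing
        ``"fail"`` (default) raises on any missing genotype; ``"drop-subject"``
        removes affected rows and logs how many were dropped.
    recode
        Optional explicit mapping from non-standard genotype tokens to the
        0/1/2 coding, applied before validation.

    Row and column order are preserved exactly as on disk.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    if class_column not in df.columns:
        raise ValueError(
            f"class column {class_column!r} not found in {path.name}; "
            f"columns are {list(df.columns)}"
        )
    snp_cols = [c for c in df.columns if c != class_column]
    if not snp_cols:
        raise ValueError(f"{path.name} has no genotype columns")
    geno_raw = df[snp_cols].to_numpy(dtype=object)
    if recode:
        for token, code in recode.items():
            geno_raw[geno_raw == token] = str(code)
    missing_mask = np.isin(geno_raw, sorted(_MISSING_TOKENS))
    if missing_mask.any():
        cells = [
            f"row {r + 1}, column {snp_cols[c]}"
            for r, c in np.argwhere(missing_mask)[:10]
        ]
        if missing == "fail":
            raise ValueError(
                f"{int(missing_mask.sum())} missing genotype value(s) in "
                f"{path.name} (policy 'fail'): {'; '.join(cells)}"
            )
        if missing != "drop-subject":
            raise ValueError("missing policy must be 'fail' or 'drop-subject'")
        drop_rows = missing_mask.any(axis=1)
        log.info(
            "dropping %d subject(s) with missing genotypes from %s",
            int(drop_rows.sum()), path.name,
        )
        df = df.loc[~drop_rows].reset_index(drop=True)
        geno_raw = geno_raw[~drop_rows]
    valid = np.isin(geno_raw, ["0", "1", "2"])
    if not valid.all():
        r, c = np.argwhere(~valid)[0]
        raise ValueError(
            f"unparseable genotype code {geno_raw[r, c]!r} at row {r + 1}, "
            f"column {snp_cols[c]} of {path.name}"
        )
    genotypes = geno_raw.astype(np.int8)
    pheno_raw = df[class_column].to_numpy(dtype=object)
    if not np.isin(pheno_raw, ["0", "1"]).all():
        bad = sorted(set(pheno_raw) - {"0", "1"})
        raise ValueError(
            f"phenotype column {class_column!r} is not binary 0/1; "
            f"found {bad[:5]}"
        )
    phenotype = pheno_raw.astype(np.int8)
    data = GenotypeDataset(
        genotypes=genotypes, phenotype=phenotype, snp_labels=snp_cols
    )
    log.info(
        "loaded %s: N=%d subjects, M=%d SNPs, %d cases / %d controls "
        "(case fraction %.3f)",
        path.name, data.n_subjects, data.n_snps, data.n_cases,
        data.n_controls, data.case_fraction,
    )
    return data


def write_genotype_table(
    data: GenotypeDataset, path: str | Path, dialect: str = "mdr-flat",
    class_column: str = "Class",
) -> None:
    """Write a dataset back to the flat-file format (inverse of the reader)."""
    df = pd.DataFrame(data.genotypes, columns=data.snp_labels)
    df[class_column] = data.phenotype
    df.to_csv(path, sep=_sep(dialect), index=False)


def write_interaction_results(
    results: list[InteractionResult],
    path: str | Path,
    snp_labels: list[str] | None = None,
) -> None:
    """Serialize interaction results as TSV, one row per locus combination.

    Columns: the interaction label, each calibrated statistic with its 95%
    interval, and the primary statistic's permutation p-value and FDR.
    """
    if not results:
        raise ValueError("refusing to write an empty result table")
    rows = []
    for r in results:
        labels = (
            "+".join(r.spec.labels(snp_labels))
            if snp_labels
            else "+".join(str(i) for i in r.spec.loci)
        )
        row: dict[str, object] = {"interaction": labels}
        for name, col in (("OR", "pOR"), ("RR", "pRR"), ("Chi", "pChi")):
            row[col] = r.corrected[name]
            row[f"{col}_ci_low"], row[f"{col}_ci_high"] = r.ci[name]
        row["pvalue"] = r.pvalue
        row["fdr"] = r.fdr
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_interaction_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back into a data frame (column-compatible)."""
    return pd.read_csv(path, sep="\t")


def write_risk_scores(
    profile: RiskScoreProfile,
    path: str | Path,
    subject_ids: list[str],
    phenotype: np.ndarray,
) -> None:
    """Write per-subject risk scores as TSV: subject_id, score, phenotype."""
    if len(subject_ids) != len(profile.scores):
        raise ValueError("subject id count does not match score count")
    df = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "score": np.asarray(profile.scores, dtype=np.int64),
            "phenotype": np.asarray(phenotype, dtype=np.int64),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_risk_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
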