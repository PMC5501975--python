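"""File formats: expression TSV, sample classes, FASTA, dose tables,
ranked-target tables.

Expression tables are tab-separated, first column ``gene_id``, header
row of sample ids, UTF-8, decimal point, scientific notation accepted
on read.  Lines starting with ``#`` are header comments (runs stamp a
config hash and seed there) and are ignored on read.  The ranked table
round-trips its key p-value columns at full float precision (exact
decimal ``repr``); other numeric columns are written with 6 significant
digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .cohort_stats import Cohort, GeneCohortStats
from .median_effect import DoseResponseSeries
from .meta_rank import RankedTarget

__all__ = [
    "ParseError",
    "read_expression_table",
    "write_expression_table",
    "read_sample_classes",
    "write_sample_classes",
    "read_cohort",
    "write_cohort",
    "read_dose_response",
    "write_dose_response",
    "write_ranked_table",
    "read_ranked_table",
    "write_stats_table",
]

#: columns of the ranked table preserved at full float precision
_EXACT_COLUMNS = ("combined_p_fisher", "combined_p_stouffer", "combined_p_TN_fisher")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _data_lines(path: Path) -> list[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        lines = [
            (lineno, line.rstrip("\n"))
            for lineno, line in enumerate(fh, start=1)
            if line.strip() and not line.startswith("#")
        ]
    if not lines:
        raise ParseError(f"{path}: empty input (no data lines)")
    return lines


def read_expression_table(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV into a float DataFrame."""
    path = Path(path)
    lines = _data_lines(path)
    header_no, header = lines[0]
    cols = header.split("\t")
    if len(cols) < 2:
        raise ParseError(f"{path}:{header_no}: header needs gene_id + >=1 sample")
    samples = cols[1:]
    dup = {s for s in samples if samples.count(s) > 1}
    if dup:
        raise ParseError(f"{path}:{header_no}: duplicate sample ids {sorted(dup)}")
    genes: list[str] = []
    seen: set[str] = set()
    values: list[list[float]] = []
    for lineno, line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != len(cols):
            raise ParseError(
                f"{path}:{lineno}: expected {len(cols)} fields, got {len(parts)}"
            )
        g = parts[0]
        if g in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene id {g!r}")
        seen.add(g)
        try:
            row = [float(v) if v not in ("", "NA", "nan") else np.nan for v in parts[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        genes.append(g)
        values.append(row)
    if not genes:
        raise ParseError(f"{path}: no gene rows")
    return pd.DataFrame(values, index=genes, columns=samples)


def write_expression_table(path, matrix: pd.DataFrame, header_comment: str = "") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("gene_id\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for g, row in matrix.iterrows():
            fh.write(str(g) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_sample_classes(path) -> pd.DataFrame:
    """Read a sample-class TSV: sample_id, class in {tumor, normal}, matched 0/1."""
    path = Path(path)
    lines = _data_lines(path)
    rows = []
    start = 1 if lines[0][1].startswith("sample_id") else 0
    seen: set[str] = set()
    for lineno, line in lines[start:]:
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
        sid, cls, matched = parts
        if sid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        seen.add(sid)
        if cls not in ("tumor", "normal"):
            raise ParseError(f"{path}:{lineno}: class must be tumor/normal, got {cls!r}")
        if matched not in ("0", "1"):
            raise ParseError(f"{path}:{lineno}: matched must be 0 or 1, got {matched!r}")
        rows.append({"sample_id": sid, "class": cls, "matched": int(matched)})
    if not rows:
        raise ParseError(f"{path}: no sample rows")
    return pd.DataFrame(rows).set_index("sample_id")


def write_sample_classes(path, cohort: Cohort, header_comment: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("sample_id\tclass\tmatched\n")
        for s in cohort.mrna.columns:
            fh.write(
                f"{s}\t{cohort.sample_class[s]}\t{1 if s in cohort.matched else 0}\n"
            )


def write_cohort(outdir, cohort: Cohort, header_comment: str = "") -> dict[str, Path]:
    """Write one cohort as mRNA TSV, optional miRNA TSV and class TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = outdir / f"{cohort.name}_mrna.tsv"
    write_expression_table(p, cohort.mrna, header_comment)
    paths["mrna"] = p
    if cohort.mirna is not None:
        p = outdir / f"{cohort.name}_mirna.tsv"
        write_expression_table(p, cohort.mirna.to_frame().T.set_axis(["miRNA"]), header_comment)
        paths["mirna"] = p
    p = outdir / f"{cohort.name}_samples.tsv"
    write_sample_classes(p, cohort, header_comment)
    paths["samples"] = p
    return paths


def read_cohort(
    name: str, mrna_path, samples_path, mirna_path=None
) -> Cohort:
    """Assemble a Cohort from the TSV dialect written by write_cohort."""
    mrna = read_expression_table(mrna_path)
    classes = read_sample_classes(samples_path)
    missing = [s for s in mrna.columns if s not in classes.index]
    if missing:
        raise ParseError(f"{samples_path}: samples without class: {missing[:5]}")
    mirna = None
    matched: frozenset[str] = frozenset()
    if mirna_path is not None:
        mir_tab = read_expression_table(mirna_path)
        mirna = mir_tab.iloc[0]
        matched = frozenset(
            s for s in classes.index[classes["matched"] == 1] if s in mirna.index
        )
    return Cohort(
        name=name,
        mirna=mirna,
        mrna=mrna,
        sample_class=classes["class"],
        matched=matched,
    )


def read_dose_response(path, drugs: tuple[str, ...] = ()) -> DoseResponseSeries:
    """Read a dose-response TSV: dose_drug1 [dose_drug2] fa."""
    path = Path(path)
    lines = _data_lines(path)
    header = lines[0][1].split("\t")
    if header[-1] != "fa" or len(header) not in (2, 3):
        raise ParseError(
            f"{path}:{lines[0][0]}: expected columns dose_drug1 [dose_drug2] fa"
        )
    ncol = len(header)
    doses, fas = [], []
    for lineno, line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != ncol:
            raise ParseError(f"{path}:{lineno}: expected {ncol} fields")
        try:
            vals = [float(v) for v in parts]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        doses.append(vals[:-1] if ncol == 3 else vals[0])
        fas.append(vals[-1])
    if not fas:
        raise ParseError(f"{path}: no data rows")
    if ncol == 2:
        labels = drugs or (header[0].removeprefix("dose_"),)
        return DoseResponseSeries(
            drugs=labels, doses=np.array(doses), fa=np.array(fas), design="single"
        )
    labels = drugs or tuple(h.removeprefix("dose_") for h in header[:2])
    return DoseResponseSeries(
        drugs=labels,
        doses=np.array(doses),
        fa=np.array(fas),
        design="non_constant_ratio",
    )


def write_dose_response(path, series: DoseResponseSeries, header_comment: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        if series.design == "single":
            fh.write(f"dose_{series.drugs[0]}\tfa\n")
            for d, f in zip(series.doses, series.fa):
                fh.write(f"{float(d)!r}\t{float(f)!r}\n")
        else:
            fh.write(f"dose_{series.drugs[0]}\tdose_{series.drugs[1]}\tfa\n")
            for (d1, d2), f in zip(series.doses, series.fa):
                fh.write(f"{float(d1)!r}\t{float(d2)!r}\t{float(f)!r}\n")


def _fmt6(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return "NA"
    return f"{v:.6g}"


def ranked_table_columns(cohort_names: Sequence[str]) -> list[str]:
    cols = ["gene_id", "n_softw_pred"]
    for c in cohort_names:
        cols += [
            f"{c}_p_value_TN",
            f"{c}_FDR",
            f"{c}_log2fold_TN",
            f"{c}_r_pearson",
            f"{c}_p_value_pearson",
        ]
    cols += [
        "combined_p_fisher",
        "combined_p_stouffer",
        "combined_p_TN_fisher",
        "passes_votes",
        "passes_deregulation",
        "passes_anticorrelation",
        "rank",
        "note",
    ]
    return cols


def write_ranked_table(
    path,
    targets: Iterable[RankedTarget],
    cohort_names: Sequence[str],
    header_comment: str = "",
) -> None:
    """Write the ranked target table.

    Column naming mirrors a published target table header: per-cohort
    p_value_TN / FDR / log2fold_TN / r_pearson / p_value_pearson blocks
    plus the combined p-values, the filter flags, and the rank.
    """
    cols = ranked_table_columns(cohort_names)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(cols) + "\n")
        for t in targets:
            row: list[str] = [t.gene_id, str(t.votes)]
            for c in cohort_names:
                s = t.stats.get(c)
                if s is None:
                    row += ["NA"] * 5
                else:
                    row += [
                        _fmt6(s.p_tn),
                        _fmt6(s.fdr),
                        _fmt6(s.log2fold),
                        _fmt6(s.r),
                        _fmt6(s.p_r),
                    ]
            for v in (t.combined_p_fisher, t.combined_p_stouffer, t.combined_p_tn_fisher):
                row.append("NA" if v is None else repr(float(v)))
            row += [
                str(int(t.passes_votes)),
                str(int(t.passes_deregulation)),
                str(int(t.passes_anticorrelation)),
                "NA" if t.rank is None else str(t.rank),
                t.note,
            ]
            fh.write("\t".join(row) + "\n")


def read_ranked_table(path) -> pd.DataFrame:
    """Read a ranked table back; key p-value columns at full precision."""
    path = Path(path)
    lines = _data_lines(path)
    cols = lines[0][1].split("\t")
    rows = []
    for lineno, line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != len(cols):
            raise ParseError(f"{path}:{lineno}: expected {len(cols)} fields")
        rows.append(parts)
    df = pd.DataFrame(rows, columns=cols)
    for c in df.columns:
        if c in ("gene_id", "note"):
            continue
        # Python float() is exact for repr output; pandas' fast parser is not
        df[c] = df[c].map(lambda v: np.nan if v in ("NA", "") else float(v))
    return df


def write_stats_table(path, stats: Iterable[GeneCohortStats], header_comment: str = "") -> None:
    """Per-cohort statistics TSV with published-style column names."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(
            "gene_id\tcohort\tp_value_TN\tFDR\tlog2fold_TN\tr_pearson\t"
            "p_value_pearson\tn_matched\n"
        )
        for s in stats:
            fh.write(
                "\t".join(
                    [
                        s.gene_id,
                        s.cohort,
                        repr(float(s.p_tn)),
                        repr(float(s.fdr)),
                        repr(float(s.log2fold)),
                        _fmt6(s.r),
                        "NA" if s.p_r is None else repr(float(s.p_r)),
                        str(s.n_matched),
                    ]
                )
                + "\n"
            )


def write_fasta(path, records) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_json(path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
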