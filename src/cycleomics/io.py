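"""Plain-text readers and writers for every pipeline format.

All tabular outputs are TSV with a header line; writers can prepend a
commented provenance line (``# key=value ...``) which readers skip.  Gene
sets travel as GMT (name, description, members), ChIP peaks as BED6.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import TimecourseMatrix
from .errors import InvalidInputError


def _provenance_line(meta: dict | None) -> str:
    if not meta:
        return ""
    return "# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n"


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None, index: bool = False):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_line(meta))
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# -- time-course matrices ---------------------------------------------------


def write_timecourse(tc: TimecourseMatrix, expr_path, samples_path, meta=None):
    """Write the expression matrix (genes × samples) and sample metadata."""
    write_tsv(tc.values, expr_path, meta={**(meta or {}), "scale": tc.scale}, index=True)
    samples = tc.samples.copy()
    samples.index.name = "sample_id"
    write_tsv(samples, samples_path, index=True)


def read_timecourse(expr_path, samples_path, scale: str | None = None) -> TimecourseMatrix:
    """Read an expression TSV plus sample metadata back into a container.

    The scale is taken from the expression file's provenance line unless
    given explicitly.
    """
    if scale is None:
        with open(expr_path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if token.startswith("scale="):
                    scale = token.split("=", 1)[1]
        if scale is None:
            raise InvalidInputError(
                "scale not found in file header; pass scale= explicitly"
            )
    values = read_tsv(expr_path, index_col=0)
    samples = read_tsv(samples_path, index_col=0)
    values.columns.name = samples.index.name = "sample_id"
    return TimecourseMatrix(values=values, samples=samples, scale=scale)


# -- gene sets (GMT) --------------------------------------------------------


def write_gmt(sets: dict, path, description: str = "na"):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *map(str, members)]) + "\n")


def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InvalidInputError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = fields[2:]
    return sets


# -- peaks / TSS / edges / homology ----------------------------------------

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed6(peaks: pd.DataFrame, path):
    df = peaks.copy()
    if "name" not in df:
        df["name"] = [f"peak{i}" for i in range(len(df))]
    if "strand" not in df:
        df["strand"] = "."
    df = df[BED6_COLUMNS]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED6_COLUMNS)]
    df.columns = BED6_COLUMNS[: df.shape[1]]
    if (df["start"] >= df["end"]).any():
        raise InvalidInputError("BED intervals must satisfy start < end")
    return df


def write_tss(tss: pd.DataFrame, path):
    out = tss.reset_index() if tss.index.name == "gene_id" else tss
    write_tsv(out, path)


def read_tss(path) -> pd.DataFrame:
    return read_tsv(path).set_index("gene_id")


def read_edges(path) -> pd.DataFrame:
    """TF→target edge TSV; an optional third (mode) column is ignored."""
    df = read_tsv(path)
    return df.iloc[:, :2].set_axis(["tf_id", "target_id"], axis=1)


def read_homology(path) -> pd.DataFrame:
    df = read_tsv(path)
    return df.iloc[:, :2].set_axis(["source_id", "target_id"], axis=1)
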