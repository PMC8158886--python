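"""File formats: TSV tables with provenance headers, GMT set files, JSON.

All tables are tab-separated with ``.`` decimals and ``NA`` for missing
values, preceded by ``#``-prefixed header comments carrying provenance
(seed, configuration hash, tool version).  Two runs with the same
configuration produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from metabometa.cohort import REQUIRED_PHENOTYPES, CohortDataset
from metabometa.enrichment import MetaboliteSet
from metabometa.errors import ParseError, SchemaError

NA = "NA"
FLOAT_FORMAT = "%.10g"


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_table(df: pd.DataFrame, path, header: dict | None = None,
                index: bool = False) -> None:
    """Write a TSV with ``#`` provenance comments above the column header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", na_rep=NA, float_format=FLOAT_FORMAT, index=index)


def read_table(path, index_col=None) -> tuple[pd.DataFrame, dict]:
    """Read a TSV written by :func:`write_table`; returns (table, header)."""
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                header[key.strip()] = value.strip()
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t", na_values=[NA], index_col=index_col)
    return df, header


def write_cohort(dataset: CohortDataset, directory, header: dict | None = None) -> None:
    """Phenotype + abundance TSVs for one cohort (annotation written separately)."""
    directory = Path(directory)
    meta = dict(header or {})
    write_table(
        dataset.phenotypes.rename_axis("subject_id"),
        directory / f"cohort_{dataset.name}.phenotypes.tsv",
        header=meta,
        index=True,
    )
    write_table(
        dataset.abundance.rename_axis("subject_id"),
        directory / f"cohort_{dataset.name}.abundance.tsv",
        header={**meta, "log_scale": str(dataset.log_scale).lower()},
        index=True,
    )


def read_cohort(name: str, directory, annotation: pd.DataFrame) -> CohortDataset:
    """Load one cohort from a study directory.

    The abundance file's ``log_scale`` header flag is honored.  Duplicate
    subject ids, phenotype/abundance id mismatches and missing required
    phenotype columns raise :class:`SchemaError`.
    """
    directory = Path(directory)
    pheno, _ = read_table(
        directory / f"cohort_{name}.phenotypes.tsv", index_col="subject_id"
    )
    abundance, header = read_table(
        directory / f"cohort_{name}.abundance.tsv", index_col="subject_id"
    )
    missing_cols = [c for c in REQUIRED_PHENOTYPES if c not in pheno.columns]
    if missing_cols:
        raise SchemaError(f"cohort {name}: missing phenotype columns {missing_cols!r}")
    if not pheno.index.is_unique or not abundance.index.is_unique:
        raise SchemaError(f"cohort {name}: duplicate subject ids")
    extra = abundance.index.difference(pheno.index)
    if len(extra):
        raise SchemaError(
            f"cohort {name}: abundance samples absent from phenotypes: "
            f"{list(extra[:3])!r}"
        )
    abundance = abundance.loc[pheno.index]
    return CohortDataset(
        name=name,
        phenotypes=pheno,
        abundance=abundance,
        annotation=annotation,
        log_scale=header.get("log_scale", "false") == "true",
    )


def write_gmt(sets, path) -> None:
    """GMT: one set per line — name, description, tab-separated members."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "subclass", *s.members]) + "\n")


def read_gmt(path) -> list[MetaboliteSet]:
    """Parse a GMT set-definition file.

    Duplicate members within a set are dropped with a warning; a duplicated
    set name or a line with fewer than two fields is a parse error carrying
    the line number.
    """
    sets: list[MetaboliteSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected name<TAB>description<TAB>members...",
                    line=lineno,
                )
            name, members = fields[0], fields[2:]
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}",
                                 line=lineno)
            seen.add(name)
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: duplicate members in set {name!r} dropped",
                    stacklevel=2,
                )
            sets.append(MetaboliteSet(name=name, members=tuple(unique)))
    return sets


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, set, np.ndarray)):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)!r}")
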