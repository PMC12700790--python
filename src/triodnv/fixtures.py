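"""Access to the versioned study fixture tables shipped with the package.

Four small TSVs encode the published cohort overview, the de novo pLoF
and missense variant tables and the gene-based white-matter-connectivity
GWAS p-values.  They are data, not code: stored under ``triodnv/data``
with a SHA-256 manifest, verified on load.
"""

from __future__ import annotations

import hashlib
import shutil
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DataError

FIXTURE_FILES = (
    "table1_cohort.tsv",
    "table2_plof.tsv",
    "table3_missense.tsv",
    "table4_gene_based.tsv",
)

#: genes associated with stuttering through prior multiplex-family studies
PRIOR_FAMILY_GENES = frozenset(
    {"GNPTAB", "AP4E1", "IFNAR1", "ARMC3", "ZBTB20", "PPID"}
)
#: genes implicated only via hypothesis-driven case/control follow-up;
#: excluded from the stuttering-associated gene set to avoid biasing
#: enrichments towards the mannose 6-phosphate pathway
HYPOTHESIS_DRIVEN_GENES = frozenset({"GNPTG", "NAGPA"})


def _data_dir():
    return resources.files("triodnv") / "data"


def _load_manifest() -> dict[str, str]:
    out = {}
    for line in (_data_dir() / "MANIFEST.sha256").read_text().splitlines():
        digest, name = line.split()
        out[name] = digest
    return out


def load_fixture(name: str, verify: bool = True) -> pd.DataFrame:
    if name not in FIXTURE_FILES:
        raise DataError(f"unknown fixture {name!r}")
    raw = (_data_dir() / name).read_bytes()
    if verify:
        expected = _load_manifest()[name]
        actual = hashlib.sha256(raw).hexdigest()
        if actual != expected:
            raise DataError(f"fixture {name} checksum mismatch")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t", dtype=str, keep_default_na=False)


def load_cohort_table() -> pd.DataFrame:
    df = load_fixture("table1_cohort.tsv")
    for c in df.columns[1:]:
        df[c] = df[c].astype(int)
    return df


def load_plof_table() -> pd.DataFrame:
    df = load_fixture("table2_plof.tsv")
    for c in ("pli", "loeuf", "maf"):
        df[c] = df[c].astype(float)
    return df


def load_missense_table() -> pd.DataFrame:
    df = load_fixture("table3_missense.tsv")
    for c in ("mis_z", "maf", "gerp"):
        df[c] = df[c].astype(float)
    df["consurf"] = df["consurf"].astype(int)
    return df


def load_gene_based_table() -> pd.DataFrame:
    df = load_fixture("table4_gene_based.tsv")
    df["n_snps"] = df["n_snps"].astype(int)
    df["p_node"] = df["p_node"].astype(float)
    df["p_edge"] = df["p_edge"].astype(float)
    return df


def emit_paper_fixtures(out_dir: str | Path) -> list[Path]:
    """Copy the versioned fixture bundle (and manifest) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in FIXTURE_FILES + ("MANIFEST.sha256",):
        target = out_dir / name
        target.write_bytes((_data_dir() / name).read_bytes())
        written.append(target)
    return written
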