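"""Readers and writers for every external format the pipeline touches.

All readers normalize dialect drift (column synonyms, tab/comma delimiters,
``chr`` prefixes) into the domain types in :mod:`eqtl2drug.models` and return
a :class:`~eqtl2drug.models.ParseReport` alongside the records, so that
``n_read == n_kept + n_dropped`` is auditable for every file.  Readers are
deterministic: the same file bytes always yield the same records in the same
order.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError
from .models import (
    CandidatePair,
    DesiredAction,
    DrugInteraction,
    EqtlAssociation,
    GeneAnnotation,
    GwasRecord,
    OrthologRecord,
    ParseReport,
)

log = logging.getLogger(__name__)

_ALLELE_RE = re.compile(r"^[ACGT]+$")
_KNOWN_BUILDS = {"b37", "b38", "hg19", "hg38"}

#: truthy spellings of drug-approval flags across interaction-db exports
_APPROVED_TOKENS = {"true", "1", "approved", "yes"}

CANDIDATE_COLUMNS = [
    "gene",
    "gene_id",
    "tissue",
    "rsid",
    "odds_ratio",
    "slope",
    "q_value",
    "desired_action",
    "drug",
    "interaction_type",
    "approved",
    "priority_flags",
]

MATCHED_TARGET_COLUMNS = [
    "rsid",
    "gene",
    "gene_id",
    "tissue",
    "beta",
    "odds_ratio",
    "slope",
    "q_value",
    "harmonization",
    "desired_action",
]


# ---------------------------------------------------------------------------
# low-level helpers


def _sniff_delimiter(path: Path) -> str:
    """Auto-detect tab vs comma from the header line (tab wins on a draw)."""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return "\t"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"empty input file: {path}") from None
    if df.empty:
        raise EmptyInputError(f"no data rows in: {path}")
    return df


def _resolve_column(df: pd.DataFrame, synonyms: Sequence[str]) -> Optional[str]:
    lower = {c.lower().strip(): c for c in df.columns}
    for name in synonyms:
        if name in lower:
            return lower[name]
    return None


def normalize_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper() if c.upper() in {"X", "Y", "MT", "M"} else c


# ---------------------------------------------------------------------------
# variant ids


def parse_variant_id(variant_id: str):
    """Parse ``chr{c}_{pos}_{ref}_{alt}_{build}`` into its components.

    Returns ``(chrom, pos, ref, alt, build)`` with the ``chr`` prefix
    stripped and a 1-based integer position.  Raises ``ValueError`` on a
    malformed id.
    """
    parts = str(variant_id).split("_")
    if len(parts) != 5:
        raise ValueError(f"malformed variant_id (expected 5 '_' fields): {variant_id!r}")
    chrom, pos_s, ref, alt, build = parts
    if not pos_s.isdigit():
        raise ValueError(f"non-numeric position in variant_id: {variant_id!r}")
    ref, alt = ref.upper(), alt.upper()
    if not (_ALLELE_RE.match(ref) and _ALLELE_RE.match(alt)):
        raise ValueError(f"non-ACGT alleles in variant_id: {variant_id!r}")
    return normalize_chrom(chrom), int(pos_s), ref, alt, build


def format_variant_id(chrom: str, pos: int, ref: str, alt: str, build: str = "b38") -> str:
    return f"chr{chrom}_{pos}_{ref}_{alt}_{build}"


# ---------------------------------------------------------------------------
# GWAS summary statistics

_GWAS_SYNONYMS = {
    "rsid": ("rsid", "rs", "snp", "snp_id", "markername", "variant"),
    "chrom": ("chrom", "chr", "chromosome"),
    "pos": ("pos", "position", "bp", "base_pair_location"),
    "other_allele": ("other_allele", "ref", "reference_allele", "a2", "allele2", "non_effect_allele"),
    "effect_allele": ("effect_allele", "alt", "alternative_allele", "a1", "allele1"),
    "odds_ratio": ("odds_ratio", "or", "o.r", "o. r", "oddsratio"),
    "beta": ("beta", "b", "effect", "log_or", "effect_size"),
    "p_value": ("p_value", "p", "pval", "p-value", "pvalue", "p.value"),
}


def read_gwas_summary(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    effect_scale: str = "odds_ratio",
):
    """Read GWAS summary statistics into :class:`GwasRecord` objects.

    ``effect_scale`` declares whether the effect column is an odds ratio
    (converted to beta = ln OR) or already a log-odds beta.  The input is
    assumed to report the effect per copy of the Alt/effect allele; supply
    ``column_map`` (field name -> source column) to override any column.
    Rows with unparseable p-values or effects, out-of-range p, non-positive
    odds ratios, or non-ACGT alleles are dropped and counted; duplicate
    rsids keep the record with the smallest p-value.

    Returns ``(records, ParseReport)``.
    """
    if effect_scale not in {"odds_ratio", "beta"}:
        raise ConfigurationError(f"effect_scale must be odds_ratio or beta, got {effect_scale!r}")
    df = _read_table(path)

    fields = ["rsid", "chrom", "pos", "other_allele", "effect_allele", "p_value"]
    effect_field = "odds_ratio" if effect_scale == "odds_ratio" else "beta"
    resolved = {}
    for fieldname in fields + [effect_field]:
        if column_map and fieldname in column_map:
            src = column_map[fieldname]
            if src not in df.columns:
                raise ConfigurationError(
                    f"mapped column {src!r} for field {fieldname!r} not found in {path}"
                )
            resolved[fieldname] = src
        else:
            src = _resolve_column(df, _GWAS_SYNONYMS[fieldname])
            if src is None:
                raise ConfigurationError(
                    f"could not find a column for field {fieldname!r} in {path}; "
                    f"tried {_GWAS_SYNONYMS[fieldname]}"
                )
            resolved[fieldname] = src

    n_read = len(df)
    work = pd.DataFrame(
        {
            "rsid": df[resolved["rsid"]].astype(str).str.strip(),
            "chrom": df[resolved["chrom"]].map(normalize_chrom),
            "pos": pd.to_numeric(df[resolved["pos"]], errors="coerce"),
            "other_allele": df[resolved["other_allele"]].astype(str).str.strip().str.upper(),
            "effect_allele": df[resolved["effect_allele"]].astype(str).str.strip().str.upper(),
            "effect": pd.to_numeric(df[resolved[effect_field]], errors="coerce"),
            "p_value": pd.to_numeric(df[resolved["p_value"]], errors="coerce"),
        }
    )

    details: dict = {}
    bad_p = work["p_value"].isna() | ~((work["p_value"] > 0) & (work["p_value"] <= 1))
    bad_effect = work["effect"].isna() | ~np.isfinite(work["effect"].to_numpy(dtype=float))
    if effect_scale == "odds_ratio":
        bad_effect |= work["effect"] <= 0
    bad_pos = work["pos"].isna() | (work["pos"] < 1)
    bad_allele = ~(
        work["other_allele"].str.match(_ALLELE_RE)
        & work["effect_allele"].str.match(_ALLELE_RE)
    )
    details["unparseable_p"] = int(bad_p.sum())
    details["unparseable_effect"] = int((bad_effect & ~bad_p).sum())
    details["bad_position"] = int((bad_pos & ~bad_p & ~bad_effect).sum())
    details["bad_allele"] = int((bad_allele & ~bad_p & ~bad_effect & ~bad_pos).sum())
    keep = work[~(bad_p | bad_effect | bad_pos | bad_allele)].copy()

    # duplicate rsids: keep the smallest p (first occurrence breaks ties)
    best = keep.groupby("rsid", sort=False)["p_value"].idxmin()
    n_dedup = len(keep) - len(best)
    details["duplicate_rsid"] = n_dedup
    keep = keep.loc[sorted(best)]

    if effect_scale == "odds_ratio":
        keep["beta"] = np.log(keep["effect"].to_numpy(dtype=float))
    else:
        keep["beta"] = keep["effect"].to_numpy(dtype=float)

    records = [
        GwasRecord(
            rsid=r.rsid,
            chrom=r.chrom,
            pos=int(r.pos),
            other_allele=r.other_allele,
            effect_allele=r.effect_allele,
            beta=float(r.beta),
            p_value=float(r.p_value),
        )
        for r in keep.itertuples(index=False)
    ]
    report = ParseReport(
        n_read=n_read,
        n_kept=len(records),
        n_dropped=n_read - len(records),
        n_deduplicated=n_dedup,
        details=details,
    )
    if report.n_dropped:
        log.info("read_gwas_summary(%s): dropped %d/%d rows (%s)", path, report.n_dropped, n_read, details)
    return records, report


# ---------------------------------------------------------------------------
# GTEx-style significant variant-gene pairs

_EQTL_SYNONYMS = {
    "variant_id": ("variant_id", "variant"),
    "gene_id": ("gene_id", "gene", "phenotype_id"),
    "slope": ("slope", "beta"),
    "q_value": ("qval", "q_value", "qvalue", "q"),
}


def read_gtex_eqtl(
    paths: Iterable,
    tissue_from_filename: bool = True,
    tissues: Optional[Sequence[str]] = None,
):
    """Read one or more significant variant-gene association files.

    The tissue label comes from each filename stem (text before the first
    ``.``) unless explicit ``tissues`` labels are given.  Variant ids are
    parsed into coordinates and alleles; malformed ids drop the row (counted
    in the report), unknown build suffixes keep the row with a warning.

    Returns ``(associations, ParseReport)`` pooled over all files.
    """
    paths = [Path(p) for p in paths]
    if tissues is not None and len(tissues) != len(paths):
        raise ConfigurationError(
            f"{len(tissues)} tissue labels for {len(paths)} files"
        )
    associations = []
    n_read = n_malformed = 0
    for i, path in enumerate(paths):
        if tissues is not None:
            tissue = tissues[i]
        elif tissue_from_filename:
            tissue = path.name.split(".")[0]
        else:
            raise ConfigurationError("tissue_from_filename=False requires explicit tissues")
        df = _read_table(path)
        resolved = {}
        for fieldname, syn in _EQTL_SYNONYMS.items():
            src = _resolve_column(df, syn)
            if src is None:
                raise ConfigurationError(f"missing column for {fieldname!r} in {path}")
            resolved[fieldname] = src
        symbol_col = _resolve_column(df, ("gene_name", "gene_symbol", "symbol"))
        n_read += len(df)
        warned_build = False
        for r in df.itertuples(index=False):
            row = r._asdict() if hasattr(r, "_asdict") else dict(zip(df.columns, r))
            vid = str(getattr(r, resolved["variant_id"], None) or row[resolved["variant_id"]])
            try:
                chrom, pos, ref, alt, build = parse_variant_id(vid)
                slope = float(row[resolved["slope"]])
                qval = float(row[resolved["q_value"]])
                if not (math.isfinite(slope) and math.isfinite(qval) and qval >= 0):
                    raise ValueError("non-finite slope or q")
            except (ValueError, TypeError):
                n_malformed += 1
                continue
            if build not in _KNOWN_BUILDS and not warned_build:
                log.warning("%s: unknown build suffix %r in variant ids (rows kept)", path, build)
                warned_build = True
            associations.append(
                EqtlAssociation(
                    variant_id=vid,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    build=build,
                    gene_id=str(row[resolved["gene_id"]]),
                    tissue=tissue,
                    slope=slope,
                    q_value=qval,
                    gene_symbol=str(row[symbol_col]) if symbol_col else None,
                )
            )
    report = ParseReport(
        n_read=n_read,
        n_kept=len(associations),
        n_dropped=n_malformed,
        details={"malformed": n_malformed},
    )
    if n_malformed:
        log.info("read_gtex_eqtl: dropped %d malformed rows", n_malformed)
    return associations, report


# ---------------------------------------------------------------------------
# drug-gene interactions (interactions.tsv dialect)

_DGIDB_SYNONYMS = {
    "gene": ("gene_name", "gene", "gene_claim_name"),
    "drug": ("drug_name", "drug", "drug_claim_primary_name"),
    "types": ("interaction_types", "interaction_type", "type"),
}
_TYPE_SPLIT_RE = re.compile(r"[,;|/]")


def read_dgidb_interactions(path):
    """Read an ``interactions.tsv``-dialect drug-gene interaction table.

    Multi-valued interaction types are split and lower-cased; the approval
    column (if present) accepts any of true/1/approved/yes case-insensitively.
    Rows with an empty gene or drug are dropped and counted, and
    (gene, drug, type) rows are de-duplicated (approval is OR-ed across
    duplicates).  Returns ``(interactions, ParseReport)``.
    """
    df = _read_table(path)
    resolved = {}
    for fieldname, syn in _DGIDB_SYNONYMS.items():
        src = _resolve_column(df, syn)
        if src is None:
            raise ConfigurationError(f"missing column for {fieldname!r} in {path}")
        resolved[fieldname] = src
    approved_col = _resolve_column(df, ("approved", "drug_is_approved", "fda_approved", "approval"))
    pubchem_col = _resolve_column(df, ("pubchem_cid", "pubchem_id", "pcid"))
    if approved_col is None:
        log.warning("%s: no approval column found; all interactions marked unapproved", path)

    n_read = len(df)
    n_empty = 0
    dedup: dict = {}
    order: list = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        gene = str(row[resolved["gene"]]).strip() if pd.notna(row[resolved["gene"]]) else ""
        drug = str(row[resolved["drug"]]).strip() if pd.notna(row[resolved["drug"]]) else ""
        if not gene or not drug or gene.lower() == "nan" or drug.lower() == "nan":
            n_empty += 1
            continue
        raw_types = row[resolved["types"]]
        raw_types = "" if pd.isna(raw_types) else str(raw_types)
        types = [t.strip().lower() for t in _TYPE_SPLIT_RE.split(raw_types)]
        types = [t for t in types if t] or ["unknown"]
        approved = False
        if approved_col is not None and pd.notna(row[approved_col]):
            approved = str(row[approved_col]).strip().lower() in _APPROVED_TOKENS
        pubchem = None
        if pubchem_col is not None and pd.notna(row[pubchem_col]):
            pubchem = str(row[pubchem_col]).strip()
        for t in types:
            key = (gene.upper(), drug.upper(), t)
            if key in dedup:
                old = dedup[key]
                if approved and not old.approved:
                    dedup[key] = DrugInteraction(old.gene_symbol, old.drug_name, t, True, old.pubchem_id)
            else:
                dedup[key] = DrugInteraction(gene, drug, t, approved, pubchem)
                order.append(key)
    interactions = [dedup[k] for k in order]
    # expanded rows (one per type) can exceed n_read, so account in raw rows
    n_kept_rows = n_read - n_empty
    report = ParseReport(
        n_read=n_read,
        n_kept=n_kept_rows,
        n_dropped=n_empty,
        details={"empty_gene_or_drug": n_empty, "n_interactions": len(interactions)},
    )
    return interactions, report


# ---------------------------------------------------------------------------
# gene lists / annotation / orthologs


def read_gene_list(path) -> set:
    """Read a plain-text gene list: one symbol per line, ``#`` comments ignored."""
    symbols = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.add(line)
    if not symbols:
        log.warning("gene list %s is empty", path)
    return symbols


_GTF_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')
_GTF_GENE_NAME_RE = re.compile(r'gene_name "([^"]+)"')


def read_gene_annotation(path, fmt: Optional[str] = None):
    """Read gene intervals from BED4+ or GTF into :class:`GeneAnnotation`.

    BED is taken natively (already 0-based half-open); GTF ``gene`` features
    are converted from 1-based closed to 0-based half-open on read.  One
    record is kept per gene_id (first wins).
    """
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in {".gtf", ".gff", ".gff3"} else "bed"
    genes: dict = {}
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 4:
            raise ConfigurationError(f"BED file {path} needs at least 4 columns")
        for row in df.itertuples(index=False):
            gene_id = str(row[3])
            strand = str(row[5]) if df.shape[1] >= 6 and str(row[5]) in {"+", "-"} else "+"
            if gene_id not in genes:
                genes[gene_id] = GeneAnnotation(
                    gene_id=gene_id,
                    symbol=gene_id,
                    chrom=normalize_chrom(row[0]),
                    start=int(row[1]),
                    end=int(row[2]),
                    strand=strand,
                )
    elif fmt == "gtf":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str,
            names=["seqname", "source", "feature", "start", "end", "score", "strand", "frame", "attribute"],
        )
        for row in df[df["feature"] == "gene"].itertuples(index=False):
            m = _GTF_GENE_ID_RE.search(row.attribute or "")
            if not m:
                continue
            gene_id = m.group(1)
            mn = _GTF_GENE_NAME_RE.search(row.attribute or "")
            if gene_id not in genes:
                genes[gene_id] = GeneAnnotation(
                    gene_id=gene_id,
                    symbol=mn.group(1) if mn else gene_id,
                    chrom=normalize_chrom(row.seqname),
                    start=int(row.start) - 1,
                    end=int(row.end),
                    strand=row.strand if row.strand in {"+", "-"} else "+",
                )
    else:
        raise ConfigurationError(f"unknown annotation format {fmt!r}")
    return list(genes.values())


def read_orthologs(path):
    """Read an ortholog table: human_gene, ortholog_gene, percent_identity[, source]."""
    df = _read_table(path)
    for col in ("human_gene", "ortholog_gene", "percent_identity"):
        if _resolve_column(df, (col,)) is None:
            raise ConfigurationError(f"missing column {col!r} in {path}")
    src_col = _resolve_column(df, ("source",))
    records = []
    n_bad = 0
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        try:
            rec = OrthologRecord(
                human_gene=str(row[_resolve_column(df, ("human_gene",))]).strip(),
                ortholog_gene=str(row[_resolve_column(df, ("ortholog_gene",))]).strip(),
                percent_identity=float(row[_resolve_column(df, ("percent_identity",))]),
                source=str(row[src_col]).strip().lower() if src_col else "alignment",
            )
        except (ValueError, TypeError):
            n_bad += 1
            continue
        records.append(rec)
    if n_bad:
        log.info("read_orthologs(%s): dropped %d invalid rows", path, n_bad)
    return records


# ---------------------------------------------------------------------------
# candidate pairs / matched targets (TSV out and back)


def _write_header(fh, meta: Optional[Mapping]) -> None:
    if meta:
        for key in sorted(meta):
            fh.write(f"# {key}={meta[key]}\n")


def write_candidates(pairs: Sequence[CandidatePair], path, meta: Optional[Mapping] = None) -> None:
    """Write candidate pairs as TSV with a fixed column order.

    ``meta`` key=value pairs (seed, thresholds, version) are embedded as
    ``#`` header comments so a rerun's provenance is auditable.
    """
    with open(path, "w") as fh:
        _write_header(fh, meta)
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                "\t".join(
                    [
                        p.gene_symbol,
                        p.gene_id,
                        p.tissue,
                        p.rsid,
                        repr(p.odds_ratio),
                        repr(p.slope),
                        repr(p.q_value),
                        p.desired_action.value,
                        p.drug_name,
                        p.interaction_type,
                        "true" if p.approved else "false",
                        ",".join(sorted(p.priority_flags)),
                    ]
                )
                + "\n"
            )


def read_candidates(path):
    """Read back a candidates TSV (inverse of :func:`write_candidates`)."""
    pairs = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header != CANDIDATE_COLUMNS:
                    raise ConfigurationError(f"unexpected candidate columns in {path}: {header}")
                continue
            vals = dict(zip(header, line.split("\t")))
            flags = frozenset(f for f in vals["priority_flags"].split(",") if f)
            pairs.append(
                CandidatePair(
                    gene_symbol=vals["gene"],
                    gene_id=vals["gene_id"],
                    tissue=vals["tissue"],
                    rsid=vals["rsid"],
                    odds_ratio=float(vals["odds_ratio"]),
                    slope=float(vals["slope"]),
                    q_value=float(vals["q_value"]),
                    desired_action=DesiredAction(vals["desired_action"]),
                    drug_name=vals["drug"],
                    interaction_type=vals["interaction_type"],
                    approved=vals["approved"] == "true",
                    priority_flags=flags,
                )
            )
    return pairs


def write_matched_targets(targets, path, meta: Optional[Mapping] = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, meta)
        fh.write("\t".join(MATCHED_TARGET_COLUMNS) + "\n")
        for t in targets:
            fh.write(
                "\t".join(
                    [
                        t.rsid,
                        t.gene_symbol or "",
                        t.gene_id,
                        t.tissue,
                        repr(t.beta),
                        repr(t.odds_ratio),
                        repr(t.slope),
                        repr(t.q_value),
                        t.harmonization,
                        t.desired_action.value if t.desired_action else "",
                    ]
                )
                + "\n"
            )
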