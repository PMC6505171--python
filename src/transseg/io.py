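"""Tabular exchange formats: genotype matrix, phenotype table, marker map.

Three plain tab-delimited text formats move data between the simulator and
the analysis stages:

* **genotype matrix** — rows are markers, columns are samples (lines or
  individual plants), calls in a four-symbol alphabet: ``A`` (homozygous for
  the first parent's allele), ``H`` (heterozygous), ``B`` (homozygous for the
  second parent's allele) and a missing token (``NA`` by default).  Each
  sample carries a population label (``early`` / ``late`` / ``unselected``)
  stored in a ``#population`` header comment.
* **phenotype table** — long format, one row per scored plant:
  ``line  year  plant  dth`` (days to heading).
* **marker map** — ``marker  chrom  bp  cM``, with 1-based physical
  coordinates and genetic positions in centimorgans.

Parsers are dialect-strict (tabs only, fixed alphabets); the single escape
hatch is a configurable missing-value token.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# integer call codes used throughout the package
CALL_A = 0      # homozygous, parent-1 (A58-type) allele
CALL_H = 1      # heterozygous
CALL_B = 2      # homozygous, parent-2 (Kitaake-type) allele
CALL_NA = -1    # missing

CALL_SYMBOLS = {CALL_A: "A", CALL_H: "H", CALL_B: "B"}
SYMBOL_CALLS = {v: k for k, v in CALL_SYMBOLS.items()}

POPULATIONS = ("early", "late", "unselected")


class ParseError(ValueError):
    """Raised when an exchange file violates its format contract."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f", line {line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


def _check_unique(ids: Sequence[str], kind: str, path=None) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ParseError(f"duplicate {kind} id {i!r}", path=path)
        seen.add(i)


@dataclass
class GenotypeMatrix:
    """Marker-by-sample matrix of parental-origin genotype calls.

    ``calls`` is an int8 array with codes ``CALL_A``/``CALL_H``/``CALL_B``/
    ``CALL_NA``.  ``populations`` labels each sample as belonging to the
    early tail, the late tail, or the unselected remainder.
    """

    markers: list[str]
    samples: list[str]
    calls: np.ndarray
    populations: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.markers = list(self.markers)
        self.samples = list(self.samples)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.samples)} samples"
            )
        _check_unique(self.markers, "marker")
        _check_unique(self.samples, "sample")
        valid = np.isin(self.calls, (CALL_A, CALL_H, CALL_B, CALL_NA))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"illegal call code {self.calls[i, j]} at marker "
                f"{self.markers[i]!r}, sample {self.samples[j]!r}"
            )
        if self.populations is None:
            self.populations = np.full(len(self.samples), "unselected", dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.populations.shape != (len(self.samples),):
            raise ValueError("one population label per sample required")
        bad = set(self.populations) - set(POPULATIONS)
        if bad:
            raise ValueError(f"unknown population labels: {sorted(bad)}")
        self._marker_index = {m: i for i, m in enumerate(self.markers)}

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def marker_index(self, marker: str) -> int:
        try:
            return self._marker_index[marker]
        except KeyError:
            raise KeyError(f"marker {marker!r} not in genotype matrix") from None

    def row(self, marker: str) -> np.ndarray:
        return self.calls[self.marker_index(marker)]

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per marker."""
        if self.n_samples == 0:
            return np.ones(self.n_markers)
        return (self.calls != CALL_NA).mean(axis=1)

    def counts(self, marker: str, population: str | None = None) -> dict[str, int]:
        """Genotype-class counts for one marker, optionally within one tail."""
        row = self.row(marker)
        if population is not None:
            row = row[self.populations == population]
        return {
            "A": int((row == CALL_A).sum()),
            "H": int((row == CALL_H).sum()),
            "B": int((row == CALL_B).sum()),
            "NA": int((row == CALL_NA).sum()),
        }

    def subset_markers(self, markers: Iterable[str]) -> "GenotypeMatrix":
        idx = [self.marker_index(m) for m in markers]
        return GenotypeMatrix(
            [self.markers[i] for i in idx], self.samples,
            self.calls[idx], self.populations.copy(),
        )

    def subset_samples(self, samples: Iterable[str]) -> "GenotypeMatrix":
        pos = {s: j for j, s in enumerate(self.samples)}
        idx = [pos[s] for s in samples]
        return GenotypeMatrix(
            self.markers, [self.samples[j] for j in idx],
            self.calls[:, idx], self.populations[idx],
        )

    def to_frame(self, missing_token: str = "NA") -> pd.DataFrame:
        sym = np.empty(self.calls.shape, dtype=object)
        for code, s in CALL_SYMBOLS.items():
            sym[self.calls == code] = s
        sym[self.calls == CALL_NA] = missing_token
        return pd.DataFrame(sym, index=self.markers, columns=self.samples)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.markers == other.markers
            and self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
            and list(self.populations) == list(other.populations)
        )


@dataclass
class PhenotypeTable:
    """Plant-level days-to-heading records with derived line means.

    One row per (line, year, plant).  Line means are arithmetic means of the
    plants scored for that line in that year; downstream statistics operate
    on line means whenever line structure exists.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["line", "year", "plant", "dth"]))

    def __post_init__(self):
        df = pd.DataFrame(self.data, columns=["line", "year", "plant", "dth"]).copy()
        df["line"] = df["line"].astype(str)
        df["year"] = df["year"].astype(int)
        df["plant"] = df["plant"].astype(int)
        df["dth"] = df["dth"].astype(float)
        if len(df):
            if not np.isfinite(df["dth"]).all() or (df["dth"] <= 0).any():
                raise ValueError("DTH values must be positive and finite")
            dup = df.duplicated(["line", "year", "plant"])
            if dup.any():
                r = df[dup].iloc[0]
                raise ValueError(
                    f"duplicate phenotype record for line {r['line']!r}, "
                    f"year {r['year']}, plant {r['plant']}"
                )
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    @property
    def lines(self) -> list[str]:
        return sorted(self.data["line"].unique())

    def line_means(self, year: int | None = None) -> pd.Series:
        """Mean DTH per line (for one year, or across all records)."""
        df = self.data if year is None else self.data[self.data["year"] == year]
        return df.groupby("line")["dth"].mean()

    def subset_year(self, year: int) -> "PhenotypeTable":
        return PhenotypeTable(self.data[self.data["year"] == year])

    def concat(self, other: "PhenotypeTable") -> "PhenotypeTable":
        return PhenotypeTable(pd.concat([self.data, other.data], ignore_index=True))


@dataclass
class MarkerMap:
    """Marker coordinates: chromosome, physical bp (1-based), genetic cM."""

    data: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.data, columns=["marker", "chrom", "bp", "cM"]).copy()
        df["marker"] = df["marker"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["bp"] = df["bp"].astype(np.int64)
        df["cM"] = df["cM"].astype(float)
        _check_unique(df["marker"].tolist(), "marker")
        if len(df):
            if (df["bp"] < 0).any() or (df["cM"] < 0).any():
                raise ValueError("marker positions must be non-negative")
            dup = df.duplicated(["chrom", "bp"])
            if dup.any():
                r = df[dup].iloc[0]
                raise ValueError(
                    f"duplicate physical position chrom {r['chrom']!r} bp {r['bp']}"
                )
        self.data = df.reset_index(drop=True)
        self._index = {m: i for i, m in enumerate(self.data["marker"])}

    def __len__(self) -> int:
        return len(self.data)

    def __contains__(self, marker: str) -> bool:
        return marker in self._index

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.data["chrom"]))

    def record(self, marker: str) -> pd.Series:
        try:
            return self.data.iloc[self._index[marker]]
        except KeyError:
            raise KeyError(f"marker {marker!r} not in map") from None

    def bp(self, marker: str) -> int:
        return int(self.record(marker)["bp"])

    def on_chrom(self, chrom: str) -> pd.DataFrame:
        return self.data[self.data["chrom"] == str(chrom)]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_lines(path):
    with open(path, "rt", encoding="utf-8") as fh:
        return fh.read().splitlines()


def write_genotypes(gm: GenotypeMatrix, path, missing_token: str = "NA",
                    header_comments: Sequence[str] = ()) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        fh.write("#population\t" + "\t".join(gm.populations) + "\n")
        fh.write("marker\t" + "\t".join(gm.samples) + "\n")
        frame = gm.to_frame(missing_token)
        for marker, row in zip(gm.markers, frame.to_numpy()):
            fh.write(marker + "\t" + "\t".join(row) + "\n")


def read_genotypes(path, missing_token: str = "NA") -> GenotypeMatrix:
    lines = _read_lines(path)
    populations = None
    header = None
    markers: list[str] = []
    rows: list[list[int]] = []
    alphabet = dict(SYMBOL_CALLS)
    alphabet[missing_token] = CALL_NA
    for ln, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        if raw.startswith("#"):
            if raw.startswith("#population\t"):
                populations = raw.split("\t")[1:]
            continue
        fields = raw.split("\t")
        if header is None:
            header = fields
            if header[0] != "marker":
                raise ParseError(
                    f"header must start with 'marker', got {header[0]!r}",
                    path=path, line=ln)
            _check_unique(header[1:], "sample", path=path)
            continue
        if len(fields) != len(header):
            raise ParseError(
                f"ragged row: {len(fields)} fields, expected {len(header)}",
                path=path, line=ln)
        marker, calls = fields[0], fields[1:]
        row = []
        for j, c in enumerate(calls):
            if c not in alphabet:
                raise ParseError(
                    f"illegal call {c!r} for marker {marker!r}, "
                    f"sample {header[j + 1]!r}", path=path, line=ln)
            row.append(alphabet[c])
        markers.append(marker)
        rows.append(row)
    if header is None:
        raise ParseError("no header row found", path=path)
    samples = header[1:]
    _check_unique(markers, "marker", path=path)
    if populations is not None and len(populations) != len(samples):
        raise ParseError(
            f"#population comment has {len(populations)} labels for "
            f"{len(samples)} samples", path=path)
    calls = (np.array(rows, dtype=np.int8) if rows
             else np.empty((0, len(samples)), dtype=np.int8))
    try:
        return GenotypeMatrix(markers, samples, calls,
                              None if populations is None else np.array(populations, object))
    except ValueError as exc:
        raise ParseError(str(exc), path=path) from exc


def write_phenotypes(pt: PhenotypeTable, path,
                     header_comments: Sequence[str] = ()) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        fh.write("line\tyear\tplant\tdth\n")
        for r in pt.data.itertuples(index=False):
            fh.write(f"{r.line}\t{r.year}\t{r.plant}\t{r.dth:g}\n")


def read_phenotypes(path) -> PhenotypeTable:
    lines = _read_lines(path)
    records = []
    header_seen = False
    for ln, raw in enumerate(lines, start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if not header_seen:
            if fields != ["line", "year", "plant", "dth"]:
                raise ParseError(
                    f"expected header 'line\\tyear\\tplant\\tdth', got {raw!r}",
                    path=path, line=ln)
            header_seen = True
            continue
        if len(fields) != 4:
            raise ParseError(f"ragged row: {len(fields)} fields, expected 4",
                             path=path, line=ln)
        line_id, year, plant, dth = fields
        try:
            records.append((line_id, int(year), int(plant), float(dth)))
        except ValueError:
            raise ParseError(f"non-numeric field in {fields!r}",
                             path=path, line=ln) from None
    if not header_seen and any(l.strip() and not l.startswith("#") for l in lines):
        raise ParseError("no header row found", path=path)
    df = pd.DataFrame(records, columns=["line", "year", "plant", "dth"])
    try:
        return PhenotypeTable(df)
    except ValueError as exc:
        raise ParseError(str(exc), path=path) from exc


def write_map(mm: MarkerMap, path, header_comments: Sequence[str] = ()) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        fh.write("marker\tchrom\tbp\tcM\n")
        for r in mm.data.itertuples(index=False):
            fh.write(f"{r.marker}\t{r.chrom}\t{r.bp}\t{r.cM:g}\n")


def read_map(path) -> MarkerMap:
    lines = _read_lines(path)
    records = []
    header_seen = False
    for ln, raw in enumerate(lines, start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if not header_seen:
            if fields != ["marker", "chrom", "bp", "cM"]:
                raise ParseError(
                    f"expected header 'marker\\tchrom\\tbp\\tcM', got {raw!r}",
                    path=path, line=ln)
            header_seen = True
            continue
        if len(fields) != 4:
            raise ParseError(f"ragged row: {len(fields)} fields, expected 4",
                             path=path, line=ln)
        marker, chrom, bp, cm = fields
        try:
            records.append((marker, chrom, int(bp), float(cm)))
        except ValueError:
            raise ParseError(f"non-numeric position in {fields!r}",
                             path=path, line=ln) from None
    df = pd.DataFrame(records, columns=["marker", "chrom", "bp", "cM"])
    try:
        return MarkerMap(df)
    except ValueError as exc:
        raise ParseError(str(exc), path=path) from exc


# ---------------------------------------------------------------------------
# adapter for externally supplied study files
# ---------------------------------------------------------------------------

def read_study_genotypes(path, early_samples: Sequence[str] = (),
                         late_samples: Sequence[str] = (),
                         symbol_map: Mapping[str, str] | None = None,
                         marker_column: str | int = 0,
                         sheet: int | str = 0) -> GenotypeMatrix:
    """Adapter for a wide genotype sheet as distributed with the study.

    Reads a spreadsheet (``.xlsx``) or delimited text file whose rows are
    markers and whose remaining columns are line calls, and maps the observed
    call symbols onto the package alphabet.  ``symbol_map`` maps observed
    cell values to ``"A"``/``"H"``/``"B"``/``"NA"``; unmapped values raise.
    Samples named in ``early_samples`` / ``late_samples`` receive tail
    labels, all others are ``unselected``.
    """
    p = Path(path)
    if p.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(p, sheet_name=sheet, dtype=str)
    else:
        sep = "," if p.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(p, sep=sep, dtype=str, comment="#")
    df = df.set_index(df.columns[marker_column] if isinstance(marker_column, int)
                      else marker_column)
    symbol_map = dict(symbol_map or {})
    for s in ("A", "H", "B", "NA"):
        symbol_map.setdefault(s, s)
    calls = np.empty(df.shape, dtype=np.int8)
    codes = {"A": CALL_A, "H": CALL_H, "B": CALL_B, "NA": CALL_NA}
    for (i, j), v in np.ndenumerate(df.to_numpy()):
        key = "NA" if (v is None or (isinstance(v, float) and np.isnan(v))) else str(v).strip()
        if key not in symbol_map or symbol_map[key] not in codes:
            raise ParseError(
                f"unmapped genotype symbol {key!r} at marker "
                f"{df.index[i]!r}, sample {df.columns[j]!r}", path=path)
        calls[i, j] = codes[symbol_map[key]]
    early, late = set(early_samples), set(late_samples)
    pops = np.array(
        ["early" if s in early else "late" if s in late else "unselected"
         for s in df.columns], dtype=object)
    return GenotypeMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                          calls, pops)


def read_study_phenotypes(path, line_column: str = "line",
                          year_column: str = "year",
                          plant_column: str | None = "plant",
                          dth_column: str = "dth",
                          sheet: int | str = 0) -> PhenotypeTable:
    """Adapter for a long-format phenotype sheet (line, year, plant, DTH)."""
    p = Path(path)
    if p.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(p, sheet_name=sheet)
    else:
        sep = "," if p.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(p, sep=sep, comment="#")
    out = pd.DataFrame({
        "line": df[line_column].astype(str),
        "year": df[year_column].astype(int),
        "dth": df[dth_column].astype(float),
    })
    if plant_column is not None and plant_column in df.columns:
        out["plant"] = df[plant_column].astype(int)
    else:
        out["plant"] = out.groupby(["line", "year"]).cumcount() + 1
    return PhenotypeTable(out[["line", "year", "plant", "dth"]])
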