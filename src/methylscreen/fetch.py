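"""Optional convenience: download GEO series matrices into pipeline TSVs.

The screen's deposited series are the Infinium Methylation27 panel
(GSE28356), the U133 Plus 2.0 constitutive expression panel (GSE7127) and
the 5AzadC+TSA re-expression panel (GSE32492). ``fetch`` downloads a series
matrix and converts its sample table to the genes/probes x samples TSV
schema the pipeline reads. The pipeline itself never requires this; it is
never exercised online by the test suite.
"""

from __future__ import annotations

import gzip
import io as _io
import urllib.error
import urllib.request
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, DataError
from .io import write_matrix

SUPPORTED_ACCESSIONS = ("GSE28356", "GSE7127", "GSE32492")

_URL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/series/{stub}nnn/{acc}/matrix/"
    "{acc}_series_matrix.txt.gz"
)


def series_matrix_url(accession: str) -> str:
    if accession not in SUPPORTED_ACCESSIONS:
        raise ConfigurationError(
            f"unsupported accession {accession!r}; supported: "
            f"{', '.join(SUPPORTED_ACCESSIONS)}"
        )
    return _URL.format(stub=accession[:-3], acc=accession)


def parse_series_matrix(text: str) -> pd.DataFrame:
    """Extract the probe x sample table between the series-matrix markers."""
    lines = text.splitlines()
    try:
        begin = next(
            i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin")
        )
        end = next(
            i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end")
        )
    except StopIteration:
        raise DataError("series matrix markers not found; malformed file") from None
    block = "\n".join(lines[begin + 1 : end])
    df = pd.read_csv(_io.StringIO(block), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [c.strip('"') for c in df.columns]
    df.index.name = "probe_id"
    return df


def fetch(accession: str, out_dir: str | Path, timeout: float = 60.0) -> Path:
    """Download one supported accession and write ``<accession>.tsv``.

    Raises :class:`ConfigurationError` for unknown accessions and
    :class:`DataError` with an actionable message when the network is
    unavailable.
    """
    url = series_matrix_url(accession)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            payload = resp.read()
    except (urllib.error.URLError, OSError) as exc:
        raise DataError(
            f"could not download {accession} from GEO ({exc}); "
            "check network access or supply local TSV inputs instead"
        ) from exc
    text = gzip.decompress(payload).decode("utf-8", errors="replace")
    df = parse_series_matrix(text)
    return write_matrix(df, out_dir / f"{accession}.tsv", index_label="probe_id")
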