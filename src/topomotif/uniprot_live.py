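"""Optional live retrieval of annotated membrane proteins from UniProt.

Fetches reviewed human entries carrying the "Cell Membrane" keyword
(KW-1003) as a TSV in exactly the column dialect `read_records_tsv`
consumes, caching the download beside the requested path.  Requires
network access and is never used by the test suite or the census itself;
the exact protein counts such a download yields depend on the UniProt
release, so record the retrieval date in your provenance.
"""

from __future__ import annotations

import urllib.parse
import urllib.request
from pathlib import Path

UNIPROT_STREAM_URL = "https://rest.uniprot.org/uniprotkb/stream"

QUERY_CELL_MEMBRANE_HUMAN_REVIEWED = "(keyword:KW-1003) AND (reviewed:true) AND (organism_id:9606)"

FIELDS = "accession,id,sequence,ft_topo_dom,ft_transmem,ft_intramem"


def fetch_cell_membrane_proteome(dest: str | Path, overwrite: bool = False) -> Path:
    """Download the KW-1003 reviewed-human TSV to ``dest`` (cached)."""
    dest = Path(dest)
    if dest.exists() and not overwrite:
        return dest
    params = urllib.parse.urlencode(
        {"query": QUERY_CELL_MEMBRANE_HUMAN_REVIEWED, "format": "tsv", "fields": FIELDS}
    )
    dest.parent.mkdir(parents=True, exist_ok=True)
    with urllib.request.urlopen(f"{UNIPROT_STREAM_URL}?{params}") as resp:
        dest.write_bytes(resp.read())
    return dest
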