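"""Optional real-world study networks.

Four public networks are used for reproduction of the published summary
tables: ``football`` (NCAA Division I-A games, 2000), ``netscience``
(largest component of the network-science coauthorship graph), ``email``
(University email network) and ``power`` (Western US power grid).  None
ships with the package; :func:`fetch` downloads them from their public
archives into a data directory, and :func:`load_real` reads whatever is
already there.  The netscience graph is reduced to its largest connected
component on load; the others are used as read.
"""

from __future__ import annotations

import io
import logging
import zipfile
from pathlib import Path
from urllib.request import urlopen

import networkx as nx

from .graphio import largest_component, read_graph

logger = logging.getLogger(__name__)

__all__ = ["REAL_NETWORKS", "fetch", "load_real"]

_UMICH = "http://www-personal.umich.edu/~mejn/netdata/"

#: name -> (zip URL, member file inside the archive, local filename)
REAL_NETWORKS = {
    "football": (_UMICH + "football.zip", "football.gml", "football.gml"),
    "netscience": (_UMICH + "netscience.zip", "netscience.gml", "netscience.gml"),
    "power": (_UMICH + "power.zip", "power.gml", "power.gml"),
    "email": (
        "https://nrvis.com/download/data/email/email-univ.zip",
        "email-univ.edges",
        "email-univ.edges",
    ),
}


def fetch(name: str, data_dir: str | Path = "data/real", timeout: float = 30.0) -> Path:
    """Download one of the study networks into ``data_dir``.

    Returns the path of the extracted graph file.  Requires network
    access; already-downloaded files are reused.
    """
    if name not in REAL_NETWORKS:
        raise KeyError(f"unknown dataset {name!r}; known: {', '.join(REAL_NETWORKS)}")
    url, member, local = REAL_NETWORKS[name]
    data_dir = Path(data_dir)
    target = data_dir / local
    if target.exists():
        return target
    data_dir.mkdir(parents=True, exist_ok=True)
    logger.info("fetching %s from %s", name, url)
    with urlopen(url, timeout=timeout) as resp:
        payload = resp.read()
    with zipfile.ZipFile(io.BytesIO(payload)) as zf:
        for info in zf.infolist():
            if Path(info.filename).name == member:
                target.write_bytes(zf.read(info))
                return target
    raise OSError(f"{member} not found inside archive {url}")


def load_real(
    name: str, data_dir: str | Path = "data/real", download: bool = False
) -> nx.Graph:
    """Load a study network from ``data_dir`` (optionally fetching it)."""
    if name not in REAL_NETWORKS:
        raise KeyError(f"unknown dataset {name!r}; known: {', '.join(REAL_NETWORKS)}")
    _, _, local = REAL_NETWORKS[name]
    path = Path(data_dir) / local
    if not path.exists():
        if not download:
            raise OSError(
                f"dataset file {path} not found; run lwcent.datasets.fetch({name!r}) "
                "(network access required) or place the file there manually"
            )
        path = fetch(name, data_dir)
    g = read_graph(path)
    if name == "netscience":
        g = largest_component(g)
    return g
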