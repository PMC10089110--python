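"""Nodal dysconnection summaries and visualization export.

Given the binary matrix of significantly altered directed connections of
an n-node network, a node's raw degree is the number of altered
connections incident on it — row sum plus column sum with the diagonal
counted once — and the normalized degree divides by the maximum degree of
an n-node directed network, 2n − 1 (n−1 incoming, n−1 outgoing, one
self-connection).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .layout import NetworkLayout

__all__ = ["degree_table", "export_brainnet", "parse_brainnet"]


def degree_table(masks: dict[str, np.ndarray],
                 layout: NetworkLayout) -> pd.DataFrame:
    """Raw and normalized altered-connection degrees per subnetwork.

    ``masks`` maps network name to a binary n×n matrix (entry [t, s] = 1
    when the s→t connection is altered).  Returns one row per subnetwork
    with columns network, subnetwork, degree, normalized_degree and, when
    the layout has coordinates, x/y/z.
    """
    rows = []
    for net, labels in layout.networks:
        n = len(labels)
        M = np.asarray(masks[net])
        if M.shape != (n, n):
            raise ValueError(f"mask for {net!r} must be {n}x{n}")
        if not np.isin(M, (0, 1)).all():
            raise ValueError(f"mask for {net!r} must be binary")
        deg = M.sum(axis=0) + M.sum(axis=1) - np.diag(M)
        norm = deg / (2 * n - 1)
        for i, lab in enumerate(labels):
            row = {"network": net, "subnetwork": lab,
                   "degree": int(deg[i]),
                   "normalized_degree": float(norm[i])}
            if layout.coordinates is not None:
                x, y, z = layout.coordinates[lab]
                row.update({"x": x, "y": y, "z": z})
            rows.append(row)
    return pd.DataFrame(rows)


def export_brainnet(degrees: pd.DataFrame, path: str | Path,
                    layout: NetworkLayout) -> Path:
    """Write a BrainNet Viewer ``.node`` file (x y z color size label).

    Color encodes the network index (1-based); size is the normalized
    degree.  Requires coordinates for every subnetwork.
    """
    if not {"x", "y", "z"}.issubset(degrees.columns):
        missing = degrees["subnetwork"].tolist()
        raise ValueError(f"coordinates missing for nodes {missing}")
    net_index = {name: i + 1 for i, name in
                 enumerate(layout.network_names)}
    path = Path(path)
    lines = []
    for row in degrees.itertuples():
        lines.append(f"{row.x:.17g}\t{row.y:.17g}\t{row.z:.17g}\t"
                     f"{net_index[row.network]}\t"
                     f"{row.normalized_degree:.17g}\t{row.subnetwork}")
    path.write_text("\n".join(lines) + "\n")
    return path


def parse_brainnet(path: str | Path) -> pd.DataFrame:
    """Read a ``.node`` file back into a table (round-trip of the export)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        x, y, z, color, size, label = line.split("\t")
        rows.append({"x": float(x), "y": float(y), "z": float(z),
                     "network_index": int(color),
                     "normalized_degree": float(size),
                     "subnetwork": label})
    return pd.DataFrame(rows)
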