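"""Network layout: large-scale resting-state networks and their subnetworks.

A :class:`NetworkLayout` names an ordered set of networks, each composed of
one or more subnetworks (functional parcels).  The default layout mirrors the
seven canonical large-scale resting-state networks — subcortical (SC),
auditory (AUD), sensorimotor (SM), visual (VIS), cognitive control (COG),
default mode (DMN) and cerebellum (CB) — with 4, 2, 8, 10, 14, 9 and 3
subnetworks respectively, 50 parcels in total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = ["NetworkLayout", "make_layout", "DEFAULT_NETWORKS"]

# Canonical subnetwork labels per network.  Two parcels that share a name in
# the published nomenclature are disambiguated here (Cuneus1/Cuneus2 in VIS;
# the COG precentral parcel is qualified as COG-PreCG) because labels must be
# unique across the whole layout.
DEFAULT_NETWORKS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("SC", ("Putamen1", "Putamen2", "Thalamus", "Caudate")),
    ("AUD", ("STG1", "STG2")),
    ("SM", ("PreCG", "SPL", "R-PoCG", "L-PoCG", "ParaCL1", "ParaCL2",
            "PoCG", "SMA")),
    ("VIS", ("Cuneus1", "FFG", "CalcarineG", "Cuneus2", "SOG", "MTG",
             "LingualG", "MOG", "R-MOG", "L-MOG")),
    ("COG", ("aInsula", "RSN-SMA", "MiFG1", "MiFG2", "COG-PreCG", "IPL",
             "R.STG+IFG", "R-IPL", "pInsula", "L-IPL", "PHG", "IFG",
             "MCC", "ITG")),
    ("DMN", ("Precuneus1", "ACC", "PCC1", "PCC2", "Precuneus2", "MiFG+SFG",
             "R-AG", "L-AG", "L.MTG+IFG")),
    ("CB", ("L-CB", "R-CB", "CB")),
)


@dataclass(frozen=True)
class NetworkLayout:
    """Ordered networks with uniquely labelled subnetworks.

    Parameters
    ----------
    networks
        Ordered ``(network_name, (subnetwork_label, ...))`` pairs.
    coordinates
        Optional map ``subnetwork label -> (x, y, z)`` peak coordinates in
        millimetres (e.g. MNI space), used only for visualization export.
    """

    networks: tuple[tuple[str, tuple[str, ...]], ...]
    coordinates: Mapping[str, tuple[float, float, float]] | None = field(
        default=None)

    def __post_init__(self) -> None:
        if not self.networks:
            raise ValueError("layout must contain at least one network")
        seen: set[str] = set()
        for name, labels in self.networks:
            if len(labels) < 1:
                raise ValueError(f"network {name!r} has no subnetworks")
            for lab in labels:
                if lab in seen:
                    raise ValueError(
                        f"duplicate subnetwork label {lab!r} in layout")
                seen.add(lab)
        net_names = [name for name, _ in self.networks]
        if len(set(net_names)) != len(net_names):
            raise ValueError("duplicate network names in layout")

    @property
    def network_names(self) -> list[str]:
        return [name for name, _ in self.networks]

    @property
    def sizes(self) -> dict[str, int]:
        """Subnetwork count per network."""
        return {name: len(labels) for name, labels in self.networks}

    @property
    def n_subnetworks(self) -> int:
        return sum(len(labels) for _, labels in self.networks)

    @property
    def all_labels(self) -> list[str]:
        return [lab for _, labels in self.networks for lab in labels]

    def labels(self, network: str) -> tuple[str, ...]:
        for name, labs in self.networks:
            if name == network:
                return labs
        raise KeyError(f"unknown network {network!r}")

    def n_ec_parameters(self) -> int:
        """Total number of directed-connection parameters, sum of n_k^2."""
        return sum(len(labels) ** 2 for _, labels in self.networks)

    def to_json(self) -> str:
        payload = {
            "networks": [[name, list(labels)] for name, labels in
                         self.networks],
            "coordinates": (None if self.coordinates is None else
                            {k: list(v) for k, v in self.coordinates.items()}),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NetworkLayout":
        payload = json.loads(text)
        networks = tuple((name, tuple(labels))
                         for name, labels in payload["networks"])
        coords = payload.get("coordinates")
        if coords is not None:
            coords = {k: tuple(float(x) for x in v) for k, v in coords.items()}
        return cls(networks=networks, coordinates=coords)


def make_layout(
    spec: Sequence[tuple[str, int | Sequence[str]]] | None = None,
    coordinates: Mapping[str, tuple[float, float, float]] | None = None,
) -> NetworkLayout:
    """Build a :class:`NetworkLayout`.

    With no arguments, returns the default 7-network, 50-subnetwork layout.
    A custom ``spec`` is a sequence of ``(network_name, size)`` or
    ``(network_name, [label, ...])`` entries; integer sizes generate labels
    ``{name}{i}``.

    Raises
    ------
    ValueError
        If any size is < 1 or labels are duplicated.
    """
    if spec is None:
        return NetworkLayout(networks=DEFAULT_NETWORKS,
                             coordinates=coordinates)
    networks = []
    for name, item in spec:
        if isinstance(item, int):
            if item < 1:
                raise ValueError(f"network {name!r} size must be >= 1")
            labels = tuple(f"{name}{i + 1}" for i in range(item))
        else:
            labels = tuple(item)
        networks.append((name, labels))
    return NetworkLayout(networks=tuple(networks), coordinates=coordinates)
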