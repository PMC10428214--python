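"""Community co-membership RGB profiles.

Three reference nodes anchor the channels (defaults: red=I94, green=S64,
blue=N142). For each analysed frame, every node sharing a community with
a reference node gets that channel incremented; counts are normalised to
the 0–256 scale (a node always co-resident with the red reference scores
exactly (256, 0, 0)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import SpecError
from .network import CommunityPartition, NetworkConfig, node_labels
from .structures_io import Structure

__all__ = [
    "ReferenceSet",
    "RGBProfile",
    "rgb_accumulate",
    "export_rgb",
]


@dataclass(frozen=True)
class ReferenceSet:
    red_node: str = "I94"
    green_node: str = "S64"
    blue_node: str = "N142"

    def __post_init__(self) -> None:
        if len({self.red_node, self.green_node, self.blue_node}) != 3:
            raise SpecError("reference nodes must be three distinct node ids")


@dataclass
class RGBProfile:
    colors: dict[str, tuple[int, int, int]]
    n_frames: int


def _round_half_up(x: float) -> int:
    return int(x + 0.5)


def rgb_accumulate(
    partitions: list[CommunityPartition], refs: ReferenceSet
) -> RGBProfile:
    """Accumulate co-membership counts with the three references.

    Every partition must contain all three reference nodes; a missing
    reference raises :class:`SpecError` naming the frame index. Channel
    values are round(count × 256 / n_frames), half up.
    """
    if not partitions:
        raise SpecError("rgb_accumulate requires at least one partition")
    ref_nodes = (refs.red_node, refs.green_node, refs.blue_node)
    counts: dict[str, list[int]] = {}
    for frame_idx, part in enumerate(partitions):
        for r in ref_nodes:
            if r not in part.assignment:
                raise SpecError(
                    f"reference node {r!r} missing from partition of frame "
                    f"{frame_idx}"
                )
        ref_comms = [part.assignment[r] for r in ref_nodes]
        for node, comm in part.assignment.items():
            tally = counts.setdefault(node, [0, 0, 0])
            for ch in range(3):
                if comm == ref_comms[ch]:
                    tally[ch] += 1
    n = len(partitions)
    colors = {
        node: tuple(_round_half_up(c * 256.0 / n) for c in tally)
        for node, tally in counts.items()
    }
    return RGBProfile(colors=colors, n_frames=n)  # type: ignore[arg-type]


def _hex(channel: int) -> str:
    return f"{min(channel, 255):02X}"


def export_rgb(
    profile: RGBProfile,
    structure: Structure | None = None,
    config: NetworkConfig | None = None,
) -> tuple[str, str]:
    """Color table plus a viewer script.

    Returns (tsv_text, script_text). The TSV keeps raw 0–256 channel
    values; the hex column clamps 256 to 255 for 8-bit color only. The
    script emits one PyMOL color command per mapped residue; nodes that
    cannot be mapped onto the structure trigger a warning but keep their
    TSV row.
    """
    lines = ["node\tr\tg\tb\thex"]
    script: list[str] = ["# per-residue coloring commands (PyMOL syntax)"]

    node_to_atom: dict[str, int] = {}
    if structure is not None:
        labels, indices = node_labels(structure, config)
        node_to_atom = dict(zip(labels, indices))

    for node in sorted(profile.colors):
        r, g, b = profile.colors[node]
        hex_code = f"#{_hex(r)}{_hex(g)}{_hex(b)}"
        lines.append(f"{node}\t{r}\t{g}\t{b}\t{hex_code}")
        if structure is None:
            continue
        if node not in node_to_atom:
            warnings.warn(f"node {node!r} not mappable onto the structure")
            continue
        atom = structure.atoms[node_to_atom[node]]
        color_name = f"rgbprof_{node.replace(':', '_').replace('#', '_')}"
        rgb01 = [min(c, 255) / 255.0 for c in (r, g, b)]
        script.append(
            f"set_color {color_name}, [{rgb01[0]:.4f}, {rgb01[1]:.4f}, "
            f"{rgb01[2]:.4f}]"
        )
        script.append(
            f"color {color_name}, chain {atom.chain} and resi "
            f"{atom.residue_seq}{atom.icode}"
        )
    return "\n".join(lines) + "\n", "\n".join(script) + "\n"
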