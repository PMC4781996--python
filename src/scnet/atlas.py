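"""Region vocabulary for the 148-node Destrieux cortical parcellation.

The Destrieux scheme names 74 gyral/sulcal units per hemisphere; network
nodes are the 148 hemispheric regions, labelled here by the conventional
abbreviation with an ``lh_``/``rh_`` prefix.
"""

from __future__ import annotations

# 74 per-hemisphere region abbreviations, in atlas index order
# (frontomarginal gyrus/sulcus ... transverse temporal sulcus).
DESTRIEUX_74: tuple[str, ...] = (
    "GSF", "GSOI", "GSP", "GSS", "GSTF", "GSCA", "GSCMA", "GSCMP", "GCPD",
    "GCPV", "GC", "GFIOper", "GFIOrb", "GFIT", "GFM", "GFS", "GILSCI", "GIS",
    "GOM", "GOS", "GOTLF", "GOTML", "GOTMP", "GO", "GPIA", "GPIS", "GPS",
    "GPost", "GPCen", "GPCun", "GR", "GS", "GTSGTT", "GTSL", "GTSPP",
    "GTSPT", "GTI", "GTM", "LFAH", "LFAV", "LFP", "PO", "PT", "SCal", "SCen",
    "SCM", "SCIA", "SCII", "SCIS", "SCTA", "SCTP", "SFI", "SFM", "SFS",
    "SIPJ", "SIPT", "SOML", "SOST", "SOA", "SOTL", "SOTML", "SOL", "SOMO",
    "SOHS", "SPO", "SPer", "SPost", "SPIP", "SPSP", "SSO", "SSP", "STI",
    "STS", "STT",
)

N_REGIONS = 2 * len(DESTRIEUX_74)


def destrieux_labels() -> list[str]:
    """Return the 148 node labels: left hemisphere first, then right."""
    return [f"{hemi}_{abbr}" for hemi in ("lh", "rh") for abbr in DESTRIEUX_74]


def region_labels(n_regions: int) -> list[str]:
    """Node labels for an ``n_regions``-node network.

    The full 148-region case uses the Destrieux abbreviations; any other
    size (e.g. reduced synthetic cohorts) gets generic zero-padded labels.
    """
    if n_regions == N_REGIONS:
        return destrieux_labels()
    width = max(3, len(str(n_regions)))
    return [f"R{i + 1:0{width}d}" for i in range(n_regions)]
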