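"""Reference panel of the 26 global population samples used throughout.

Each panel is a 3-letter population code with its sample size and continental
super-group. The default panel is the Phase 3 set of 26 whole-genome
sequencing population samples.
"""

from __future__ import annotations

from dataclasses import dataclass

SUPER_GROUPS = ("AFR", "AMR", "EAS", "EUR", "SAS")


@dataclass(frozen=True)
class PopulationPanel:
    """One population sample: code, free-text description, n, super-group."""

    label: str
    description: str
    sample_size: int
    super_group: str

    def __post_init__(self) -> None:
        if len(self.label) != 3:
            raise ValueError(f"population label must be 3 letters, got {self.label!r}")
        if self.sample_size <= 0:
            raise ValueError("sample_size must be positive")
        if self.super_group not in SUPER_GROUPS:
            raise ValueError(f"unknown super group {self.super_group!r}")


DEFAULT_PANELS: tuple[PopulationPanel, ...] = (
    PopulationPanel("ACB", "African Caribbean in Barbados", 96, "AFR"),
    PopulationPanel("ESN", "Esan in Nigeria", 99, "AFR"),
    PopulationPanel("GWD", "Gambian in Western Division, Mandinka", 113, "AFR"),
    PopulationPanel("LWK", "Luhya in Webuye, Kenya", 99, "AFR"),
    PopulationPanel("MSL", "Mende in Sierra Leone", 85, "AFR"),
    PopulationPanel("ASW", "People with African Ancestry in Southwest USA", 61, "AFR"),
    PopulationPanel("YRI", "Yoruba in Ibadan, Nigeria", 108, "AFR"),
    PopulationPanel("CLM", "Colombians in Medellin, Colombia", 94, "AMR"),
    PopulationPanel("MXL", "People with Mexican Ancestry in Los Angeles, CA, USA", 64, "AMR"),
    PopulationPanel("PEL", "Peruvians in Lima, Peru", 85, "AMR"),
    PopulationPanel("PUR", "Puerto Ricans in Puerto Rico", 104, "AMR"),
    PopulationPanel("CDX", "Chinese Dai in Xishuangbanna, China", 93, "EAS"),
    PopulationPanel("CHB", "Han Chinese in Beijing, China", 103, "EAS"),
    PopulationPanel("JPT", "Japanese in Tokyo, Japan", 104, "EAS"),
    PopulationPanel("KHV", "Kinh in Ho Chi Minh City, Vietnam", 99, "EAS"),
    PopulationPanel("CHS", "Southern Han Chinese", 105, "EAS"),
    PopulationPanel("GBR", "British in England and Scotland", 91, "EUR"),
    PopulationPanel("FIN", "Finnish in Finland", 99, "EUR"),
    PopulationPanel("IBS", "Iberian Populations in Spain", 107, "EUR"),
    PopulationPanel("TSI", "Toscani in Italia", 107, "EUR"),
    PopulationPanel(
        "CEU",
        "Utah residents (CEPH) with Northern and Western European ancestry",
        99,
        "EUR",
    ),
    PopulationPanel("BEB", "Bengali in Bangladesh", 86, "SAS"),
    PopulationPanel("GIH", "Gujarati Indians in Houston, TX, USA", 103, "SAS"),
    PopulationPanel("ITU", "Indian Telugu in the UK", 102, "SAS"),
    PopulationPanel("PJL", "Punjabi in Lahore, Pakistan", 96, "SAS"),
    PopulationPanel("STU", "Sri Lankan Tamil in the UK", 102, "SAS"),
)

PANEL_LABELS: tuple[str, ...] = tuple(p.label for p in DEFAULT_PANELS)

EUROPEAN_LABELS: frozenset[str] = frozenset(
    p.label for p in DEFAULT_PANELS if p.super_group == "EUR"
)

AFRICAN_LABELS: frozenset[str] = frozenset(
    p.label for p in DEFAULT_PANELS if p.super_group == "AFR"
)


def panel_by_label(label: str) -> PopulationPanel:
    for p in DEFAULT_PANELS:
        if p.label == label:
            return p
    raise KeyError(f"unknown population label {label!r}")
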