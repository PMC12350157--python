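"""Morphometric feature schema.

The scorer operates on a fixed, ordered feature space of 315 structural-MRI
measures: four cortical measure classes (thickness CT, surface area SA, gray
matter volume GMV, gray:white signal intensity ratio GWR) over the 34
Desikan-Killiany regions in each hemisphere (4 x 34 x 2 = 272), plus 43
subcortical/ventricular segmentation (ASEG) volumes.  A reduced ``no_gwr``
variant (247 features) drops the GWR block for datasets that do not
distribute signal-intensity ratios.

Feature names follow the aparcstats2table / asegstats2table conventions
(``lh_bankssts_thickness``, ``Left-Hippocampus``, ...); GWR columns, which
have no canonical tabular export, use ``lh_<region>_gwr``.

The four lateralized white-matter-hypointensity measures are excluded by
construction (insufficient variance); only the whole-brain hypointensity
totals appear in the ASEG block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import SchemaError

MEASURE_CLASSES = ("CT", "SA", "GMV", "GWR", "ASEG")
HEMISPHERES = ("left", "right", "midline")

#: The 34 Desikan-Killiany cortical parcels (FreeSurfer naming).
DK_REGIONS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
)

_CORTICAL_SUFFIX = {"CT": "thickness", "SA": "area", "GMV": "volume", "GWR": "gwr"}

#: Bilateral ASEG structures (prefixed Left-/Right-).
_ASEG_BILATERAL = (
    "Lateral-Ventricle", "Inf-Lat-Vent", "Cerebellum-White-Matter",
    "Cerebellum-Cortex", "Thalamus-Proper", "Caudate", "Putamen", "Pallidum",
    "Hippocampus", "Amygdala", "Accumbens-area", "VentralDC", "vessel",
    "choroid-plexus",
)

#: Midline / whole-brain ASEG measures.
_ASEG_MIDLINE = (
    "3rd-Ventricle", "4th-Ventricle", "5th-Ventricle", "Brain-Stem", "CSF",
    "Optic-Chiasm", "CC_Posterior", "CC_Mid_Posterior", "CC_Central",
    "CC_Mid_Anterior", "CC_Anterior", "WM-hypointensities",
    "non-WM-hypointensities", "BrainSegVolNotVent", "TotalGrayVol",
)

#: Lateralized hypointensity measures dropped for insufficient variance.
EXCLUDED_ASEG = (
    "Left-WM-hypointensities", "Right-WM-hypointensities",
    "Left-non-WM-hypointensities", "Right-non-WM-hypointensities",
)

N_FULL = 315
N_NO_GWR = 247


@dataclass(frozen=True)
class SchemaEntry:
    name: str
    measure_class: str
    hemisphere: str
    region: str


@dataclass
class FeatureSchema:
    """Ordered morphometric feature space (``full`` = 315, ``no_gwr`` = 247)."""

    entries: list[SchemaEntry]
    variant: str = "full"
    _index: dict[str, SchemaEntry] = field(init=False, repr=False)

    def __post_init__(self):
        names = [e.name for e in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemaError(f"duplicate feature names: {sorted(dupes)}")
        for e in self.entries:
            if e.measure_class not in MEASURE_CLASSES:
                raise SchemaError(
                    f"unknown measure class {e.measure_class!r} for {e.name!r}"
                )
            if e.hemisphere not in HEMISPHERES:
                raise SchemaError(
                    f"unknown hemisphere {e.hemisphere!r} for {e.name!r}"
                )
        bad = set(names) & set(EXCLUDED_ASEG)
        if bad:
            raise SchemaError(f"excluded-by-construction features present: {sorted(bad)}")
        object.__setattr__(self, "_index", {e.name: e for e in self.entries})

    def __len__(self):
        return len(self.entries)

    def __contains__(self, name):
        return name in self._index

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def classes(self) -> pd.Series:
        """Measure class per feature, in schema order."""
        return pd.Series(
            [e.measure_class for e in self.entries], index=self.names, name="class"
        )

    def subset(self, measure_class: str) -> list[str]:
        return [e.name for e in self.entries if e.measure_class == measure_class]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.name, e.measure_class, e.hemisphere, e.region) for e in self.entries],
            columns=["feature", "measure_class", "hemisphere", "region"],
        )


def _cortical_entries(measure_class: str) -> list[SchemaEntry]:
    suffix = _CORTICAL_SUFFIX[measure_class]
    out = []
    for hemi, prefix in (("left", "lh"), ("right", "rh")):
        for region in DK_REGIONS:
            out.append(
                SchemaEntry(f"{prefix}_{region}_{suffix}", measure_class, hemi, region)
            )
    return out


def _aseg_entries() -> list[SchemaEntry]:
    out = []
    for side, hemi in (("Left", "left"), ("Right", "right")):
        for structure in _ASEG_BILATERAL:
            out.append(SchemaEntry(f"{side}-{structure}", "ASEG", hemi, structure))
    for structure in _ASEG_MIDLINE:
        out.append(SchemaEntry(structure, "ASEG", "midline", structure))
    return out


def default_schema(variant: str = "full") -> FeatureSchema:
    """Build the built-in schema (315 features, or 247 without GWR)."""
    if variant not in ("full", "no_gwr"):
        raise SchemaError(f"unknown schema variant {variant!r}")
    classes = ["CT", "SA", "GMV"] + (["GWR"] if variant == "full" else [])
    entries: list[SchemaEntry] = []
    for mc in classes:
        entries.extend(_cortical_entries(mc))
    entries.extend(_aseg_entries())
    return FeatureSchema(entries, variant=variant)


def load_feature_schema(source) -> FeatureSchema:
    """Load a schema from a built-in name or a delimited file.

    ``source`` may be ``"default_full"``, ``"default_no_gwr"``, or a path to
    a CSV/TSV with columns (feature, measure_class, hemisphere, region) and
    an optional ``variant`` column (constant).
    """
    if source == "default_full":
        return default_schema("full")
    if source == "default_no_gwr":
        return default_schema("no_gwr")
    try:
        df = pd.read_csv(source, sep=None, engine="python")
    except (OSError, ValueError) as exc:
        raise SchemaError(f"cannot read schema from {source!r}: {exc}") from exc
    required = {"feature", "measure_class", "hemisphere", "region"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"schema file missing columns: {sorted(required - set(df.columns))}"
        )
    variant = "full"
    if "variant" in df.columns:
        uniq = df["variant"].unique()
        if len(uniq) != 1:
            raise SchemaError("schema file declares multiple variants")
        variant = str(uniq[0])
    entries = [
        SchemaEntry(str(r.feature), str(r.measure_class), str(r.hemisphere), str(r.region))
        for r in df.itertuples()
    ]
    return FeatureSchema(entries, variant=variant)
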