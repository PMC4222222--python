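"""Default region catalogue for the synthetic generator.

For each of the 43 regions routinely reported by FreeSurfer-based volumetric
studies (9 subcortical measures including CSF, 34 Desikan-Killiany cortical
parcels) we store the published scaling exponent of the region's power-law
relation to intracranial volume, the published standard error of that
exponent at n = 141, and a plausible typical volume in cc used to place the
synthetic scale constant alpha.  The typical volumes are round anatomical
magnitudes, not estimates from any particular cohort.
"""

from __future__ import annotations

# region -> (beta, se_beta, typical_volume_cc)
SUBCORTICAL: dict[str, tuple[float, float, float]] = {
    "caudate": (0.80, 0.10, 3.5),
    "putamen": (0.72, 0.08, 5.0),
    "amygdala": (0.77, 0.08, 1.6),
    "hippocampus": (0.62, 0.06, 4.0),
    "pallidum": (0.80, 0.08, 1.8),
    "accumbens": (0.95, 0.11, 0.6),
    "thalamus": (0.89, 0.07, 7.5),
    "lateral_ventricle": (1.57, 0.41, 15.0),
    "csf": (0.66, 0.19, 1.2),
}

CORTICAL: dict[str, tuple[float, float, float]] = {
    "bankssts": (0.86, 0.12, 2.5),
    "caudalanteriorcingulate": (0.69, 0.14, 1.9),
    "caudalmiddlefrontal": (0.93, 0.11, 6.5),
    "cuneus": (0.52, 0.12, 3.0),
    "entorhinal": (1.04, 0.12, 1.8),
    "fusiform": (0.80, 0.08, 9.5),
    "inferiorparietal": (0.80, 0.10, 13.0),
    "inferiortemporal": (1.06, 0.09, 10.5),
    "isthmuscingulate": (0.88, 0.10, 2.6),
    "lateraloccipital": (0.67, 0.08, 11.5),
    "lateralorbitofrontal": (0.89, 0.07, 7.5),
    "lingual": (0.57, 0.11, 6.5),
    "medialorbitofrontal": (0.94, 0.08, 5.5),
    "middletemporal": (1.00, 0.09, 11.0),
    "parahippocampal": (0.61, 0.10, 2.1),
    "paracentral": (0.71, 0.10, 3.5),
    "parsopercularis": (1.04, 0.12, 4.5),
    "parsorbitalis": (0.65, 0.11, 2.1),
    "parstriangularis": (0.94, 0.12, 3.9),
    "pericalcarine": (0.64, 0.16, 2.2),
    "postcentral": (0.88, 0.09, 10.0),
    "posteriorcingulate": (0.96, 0.09, 3.1),
    "precentral": (0.73, 0.08, 13.0),
    "precuneus": (0.91, 0.09, 9.7),
    "rostralanteriorcingulate": (1.17, 0.12, 2.4),
    "rostralmiddlefrontal": (1.04, 0.10, 16.0),
    "superiorfrontal": (0.96, 0.08, 22.0),
    "superiorparietal": (0.80, 0.10, 13.0),
    "superiortemporal": (0.89, 0.08, 11.5),
    "supramarginal": (0.94, 0.09, 10.0),
    "frontalpole": (0.68, 0.15, 0.9),
    "temporalpole": (0.52, 0.11, 2.3),
    "transversetemporal": (0.81, 0.13, 1.1),
    "insula": (1.06, 0.07, 6.7),
}

REGION_DEFAULTS: dict[str, tuple[float, float, float]] = {**SUBCORTICAL, **CORTICAL}
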