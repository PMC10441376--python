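"""Bundled knowledge-base content.

Identifiers printed with a stable MRIO/OBI/IAO prefix are carried verbatim;
classes that are named but whose IRIs are not printed receive PROVISIONAL
``MRIOKIT:`` identifiers.  Acquisition-rule facets transcribed from the
published axioms carry provenance ``PAPER``; rules this toolkit fills in
for named subtypes (FLAIR, PD, DWI, fMRI, SPGR) carry ``DEFAULT`` and are
overridable through the YAML document form of the knowledge base.

Note on one printed identifier: OBI:0003327 appears for both *image data
set* and *raw image data set* in the source material.  The bundle keeps
OBI:0003327 on *image data set* (its first introduction) and gives *raw
image data set* a provisional identifier, recording the clash in the
definition metadata.
"""

from __future__ import annotations

from .knowledge_base import (
    AnalysisSpec,
    AtlasMap,
    AtlasRegion,
    Constraint,
    KnowledgeBase,
    TermBridge,
    TermRecord,
    TypeAxiom,
)

# Widely used data-set type CURIEs
T1W = "MRIO:0000366"
T2W = "MRIO:0000367"
FLAIR = "MRIO:0000511"
SPGR = "MRIO:0000680"
PD = "MRIOKIT:pd-mri-data-set"
DWI = "MRIOKIT:dwi-mri-data-set"
FMRI = "MRIOKIT:fmri-data-set"
T1W_FOLLOWUP = "MRIOKIT:t1w-followup-data-set"
SIENAX = "MRIO:0000525"
DK_ATLAS = "MRIO:0000649"

_T = TermRecord


def _terms() -> tuple[TermRecord, ...]:
    t = []
    # --- upper-level information artifact scaffold
    t += [
        _T("IAO:0000030", "information content entity", namespace="IAO"),
        _T(
            "IAO:0000100",
            "data set",
            parent_iri="IAO:0000030",
            namespace="IAO",
        ),
        _T(
            "IAO:0000101",
            "image",
            "A two-dimensional information content entity; too narrow for "
            "volumetric biomedical imaging data.",
            parent_iri="IAO:0000030",
            namespace="IAO",
        ),
        _T("OBI:0200000", "data transformation", namespace="OBI"),
        _T("OBI:0002985", "magnetic resonance imaging assay", namespace="OBI"),
        _T("OBI:0000272", "protocol", namespace="OBI"),
        _T("OBI:0000067", "evaluant role", namespace="OBI"),
        _T(
            "OBI:0003329",
            "magnetic resonance imaging participant",
            namespace="OBI",
        ),
    ]
    # --- image data set chain
    t += [
        _T(
            "OBI:0003327",
            "image data set",
            "A data set that is comprised of multidimensional structured "
            "measurements and metadata required for a morphological "
            "representation of an entity.",
            parent_iri="IAO:0000100",
            namespace="OBI",
        ),
        _T(
            "MRIOKIT:raw-image-data-set",
            "raw image data set",
            "An image data set that encodes measurement values produced by "
            "some instrument before undergoing a data transformation. "
            "[Provisional identifier: the source material prints "
            "OBI:0003327 for this class as well as for 'image data set'; "
            "the clash is resolved in favour of the first introduction.]",
            parent_iri="OBI:0003327",
            namespace="PROVISIONAL",
        ),
        _T(
            "OBI:0003354",
            "raw magnetic resonance image data set",
            "An image data set that is the direct output of a magnetic "
            "resonance imaging assay and whose values encode spatial "
            "frequencies produced by the NMR or MRI instrument.",
            parent_iri="MRIOKIT:raw-image-data-set",
            namespace="OBI",
        ),
        _T(
            "OBI:0003333",
            "computed image data set",
            "An image data set that is the output of an image data set "
            "analysis.",
            parent_iri="OBI:0003327",
            namespace="OBI",
        ),
        _T(
            "OBI:0003334",
            "reconstructed magnetic resonance image data set",
            "An image data set that is the direct output of a raw magnetic "
            "resonance image data set reconstruction or a transformation of "
            "another magnetic resonance image data set.",
            parent_iri="OBI:0003333",
            namespace="OBI",
        ),
    ]
    # --- acquisition data-set types
    t += [
        _T(
            T1W,
            "T1 weighted magnetic resonance image data set",
            "A reconstructed magnetic resonance image data set acquired "
            "with short repetition and echo times so that contrast is "
            "dominated by spin-lattice (T1) relaxation.",
            parent_iri="OBI:0003334",
            synonyms=("T1w", "T1 weighted image data set"),
        ),
        _T(
            T2W,
            "T2 weighted magnetic resonance image data set",
            "A reconstructed magnetic resonance image data set acquired "
            "with long repetition and echo times so that contrast is "
            "dominated by spin-spin (T2) relaxation.",
            parent_iri="OBI:0003334",
            synonyms=("T2w", "T2 weighted image data set"),
        ),
        _T(
            FLAIR,
            "T2 FLAIR magnetic resonance image data set",
            "A T2 weighted data set acquired with an inversion-recovery "
            "preparation that nulls cerebrospinal fluid signal.",
            parent_iri=T2W,
            synonyms=("FLAIR", "T2 FLAIR", "T2 FLAIR image data set"),
        ),
        _T(
            SPGR,
            "T1 SPGR magnetic resonance image data set",
            "A high-resolution T1 weighted data set acquired with a spoiled "
            "gradient-recalled echo sequence.",
            parent_iri=T1W,
            synonyms=("T1 SPGR", "SPGR"),
        ),
        _T(
            PD,
            "proton density magnetic resonance image data set",
            "A reconstructed data set acquired with long repetition time "
            "and short echo time so that contrast reflects proton density.",
            parent_iri="OBI:0003334",
            namespace="PROVISIONAL",
            synonyms=("PD", "PDw", "proton density image data set"),
        ),
        _T(
            DWI,
            "diffusion weighted magnetic resonance image data set",
            "A reconstructed data set acquired with diffusion-sensitizing "
            "gradients, carrying one or more diffusion b values.",
            parent_iri="OBI:0003334",
            namespace="PROVISIONAL",
            synonyms=("DWI", "diffusion weighted image data set"),
        ),
        _T(
            FMRI,
            "functional magnetic resonance image data set",
            "A four-dimensional reconstructed data set acquired as a time "
            "series of echo-planar volumes.",
            parent_iri="OBI:0003334",
            namespace="PROVISIONAL",
            synonyms=("fMRI", "bold", "functional MRI data set"),
        ),
        _T(
            T1W_FOLLOWUP,
            "T1 weighted follow-up magnetic resonance image data set",
            "A T1 weighted data set acquired at a later timepoint of the "
            "same subject, used by longitudinal two-timepoint analyses.",
            parent_iri=T1W,
            namespace="PROVISIONAL",
            synonyms=("T1w followup",),
        ),
    ]
    # --- acquisition sequence processes
    t += [
        _T(
            "MRIO:0000385",
            "T1 weighted MRI acquisition sequence",
            "An MRI acquisition whose machine settings produce a T1 "
            "weighted magnetic resonance image data set as output.",
            parent_iri="OBI:0002985",
        ),
        _T(
            "MRIO:0000386",
            "T2 weighted MRI acquisition sequence",
            "An MRI acquisition whose machine settings produce a T2 "
            "weighted magnetic resonance image data set as output.",
            parent_iri="OBI:0002985",
        ),
    ]
    # --- acquisition parameter terms
    param_parent = "MRIO:0000342"
    t += [
        _T(
            param_parent,
            "MRI machine parameter",
            "Parameters that a technician may specify to compose a specific "
            "MRI acquisition sequence as part of a scanning protocol.",
            parent_iri="IAO:0000030",
        ),
        _T(
            "MRIO:0000364",
            "acquisition matrix",
            "The total number of independent data samples in the frequency "
            "and phase directions.",
            parent_iri=param_parent,
        ),
        _T(
            "MRIO:0000655",
            "diffusion b value",
            "Measures the degree of diffusion weighting applied, indicating "
            "the amplitude, time, and spacing of the paired gradients.",
            parent_iri=param_parent,
        ),
        _T(
            "MRIO:0000690",
            "diffusion gradient",
            "Magnetic field variations applied to determine directional "
            "vectors measuring at least three dimensions of diffusion per "
            "voxel.",
            parent_iri=param_parent,
        ),
        _T(
            "MRIO:0000358",
            "echo time",
            "The time between an excitation pulse and peak of the echo "
            "produced in magnetic resonance imaging.",
            parent_iri=param_parent,
            synonyms=("TE",),
        ),
        _T(
            "MRIO:0000359",
            "echo train length",
            "The number of spin echoes in a given unit of time.",
            parent_iri=param_parent,
        ),
        _T(
            "MRIO:0000360",
            "field of view",
            "The distance (in cm or mm) over which a magnetic resonance "
            "image is acquired or displayed.",
            parent_iri=param_parent,
        ),
        _T(
            "MRIO:0000630",
            "flip angle",
            "Angle at which a proton's axis shifts from its longitudinal "
            "plane to its transverse plane by excitation from "
            "radiofrequency pulses.",
            parent_iri=param_parent,
        ),
        _T(
            "MRIO:0000653",
            "inversion time",
            "The time elapsed between the preparatory 180 degree pulse and "
            "the 90 degree readout pulse.",
            parent_iri=param_parent,
            synonyms=("TI",),
        ),
        _T(
            "MRIO:0000369",
            "matrix size",
            "The number of data points collected in one, two, or all three "
            "directions.",
            parent_iri=param_parent,
        ),
        _T(
            "MRIO:0000687",
            "number of temporal positions",
            "Prescribed timepoints to collect in a 4D scan, resulting in n "
            "volumes.",
            parent_iri=param_parent,
        ),
        _T(
            "MRIO:0000365",
            "phase encoding",
            "Locating a magnetic resonance signal by altering the phase of "
            "spins in one dimension with a pulsed magnetic field gradient "
            "prior to acquisition.",
            parent_iri=param_parent,
        ),
        _T(
            "MRIO:0000361",
            "phase FOV",
            "The field of view in the phase encoding direction expressed "
            "as a percent of the overall field of view.",
            parent_iri=param_parent,
        ),
        _T(
            "MRIO:0000356",
            "plane",
            "The direction that the MRI image was taken.",
            parent_iri=param_parent,
        ),
        _T(
            "MRIO:0000371",
            "coronal plane",
            "The plane that divides the body into ventral and dorsal "
            "sections.",
            parent_iri="MRIO:0000356",
        ),
        _T(
            "MRIO:0000370",
            "sagittal plane",
            "The plane that divides the body into left and right sections.",
            parent_iri="MRIO:0000356",
        ),
        _T(
            "MRIO:0000372",
            "transverse plane",
            "The plane that divides the body into inferior and superior "
            "sections.",
            parent_iri="MRIO:0000356",
        ),
        _T(
            "MRIO:0000357",
            "repetition time",
            "The time from the application of an excitation pulse to the "
            "application of the next pulse; measured in milliseconds.",
            parent_iri=param_parent,
            synonyms=("TR",),
        ),
        _T(
            "MRIO:0000363",
            "slice gap",
            "The not-measured distance between the slices.",
            parent_iri=param_parent,
        ),
        _T(
            "MRIO:0000362",
            "slice thickness",
            "The distance between two 2D image matrices; the voxel "
            "measurement in the z direction.",
            parent_iri=param_parent,
        ),
        _T(
            "MRIOKIT:scanning-sequence",
            "scanning sequence",
            "The pulse sequence category used for acquisition: spin echo, "
            "gradient echo, echo planar, inversion recovery, or research "
            "mode.",
            parent_iri=param_parent,
            namespace="PROVISIONAL",
        ),
        _T(
            "MRIOKIT:spacing-between-slices",
            "spacing between slices",
            "Center-to-center distance between adjacent slices; slice gap "
            "is derived as this minus slice thickness.",
            parent_iri=param_parent,
            namespace="PROVISIONAL",
        ),
    ]
    # --- analysis class chain
    t += [
        _T(
            "OBI:0003355",
            "image data set analysis",
            "The process of deriving a data item from an image data set "
            "using computer algorithms.",
            parent_iri="OBI:0200000",
            namespace="OBI",
        ),
        _T(
            "MRIO:0000508",
            "magnetic resonance image data set analysis",
            "Any combination of digital image analysis and statistical "
            "tools that may be used to derive processed magnetic resonance "
            "images or data measurements about the magnetic resonance "
            "images.",
            parent_iri="OBI:0003355",
        ),
        _T(
            "MRIO:0000523",
            "brain volumetric analysis",
            "An MRI data set analysis estimating the volume of brain "
            "tissue or structures.",
            parent_iri="MRIO:0000508",
        ),
        _T(
            "MRIO:0000524",
            "whole brain volumetric analysis",
            "A brain volumetric analysis estimating whole-brain tissue "
            "volumes.",
            parent_iri="MRIO:0000523",
        ),
        _T(
            SIENAX,
            "SIENAX analysis",
            "Brain volumetric analysis tool for the automated estimation "
            "of grey matter, white matter, CSF, and whole brain volume "
            "from T1w MRI.",
            parent_iri="MRIO:0000524",
        ),
        _T(
            "MRIOKIT:siena-analysis",
            "SIENA analysis",
            "A brain volumetric analysis estimating percent brain volume "
            "change between two timepoints from baseline and follow-up "
            "T1w MRI.",
            parent_iri="MRIO:0000524",
            namespace="PROVISIONAL",
        ),
        _T(
            "MRIOKIT:fast-analysis",
            "FAST analysis",
            "Segmentation and volume estimation of grey matter, white "
            "matter, and CSF from T1w MRI.",
            parent_iri="MRIO:0000523",
            namespace="PROVISIONAL",
        ),
        _T(
            "MRIOKIT:first-analysis",
            "FIRST analysis",
            "Automated segmentation and volume estimation of subcortical "
            "structures from T1w MRI.",
            parent_iri="MRIO:0000523",
            namespace="PROVISIONAL",
        ),
        _T(
            "MRIOKIT:freesurfer-analysis",
            "FreeSurfer analysis",
            "Automated tissue segmentation and volumetry estimates from "
            "T1w MRI.",
            parent_iri="MRIO:0000508",
            namespace="PROVISIONAL",
        ),
        _T(
            "MRIOKIT:neurostream-analysis",
            "NeuroSTREAM analysis",
            "Automated estimation of lateral ventricle volume from "
            "clinical-quality T2 FLAIR MRI.",
            parent_iri="MRIO:0000523",
            namespace="PROVISIONAL",
        ),
        _T(
            "MRIOKIT:deepgrai-analysis",
            "DeepGRAI analysis",
            "Neural-network estimation of thalamic volume from T2 FLAIR "
            "image data sets of an entire human brain.",
            parent_iri="MRIO:0000523",
            namespace="PROVISIONAL",
        ),
        _T(
            "MRIOKIT:lpa-analysis",
            "LPA analysis",
            "A focal lesion analysis that statistically predicts the "
            "location of MS lesions in a T2w MRI.",
            parent_iri="MRIO:0000508",
            namespace="PROVISIONAL",
        ),
        _T(
            "MRIOKIT:cpac-analysis",
            "C-PAC analysis",
            "Preconfigured pipelines for fMRI analysis and functional "
            "connectomics estimation.",
            parent_iri="MRIO:0000508",
            namespace="PROVISIONAL",
        ),
        _T(
            "MRIOKIT:nemo-analysis",
            "NeMo analysis",
            "Assessment of implied network changes from patterns of white "
            "matter alteration using reference tractograms.",
            parent_iri="MRIO:0000508",
            namespace="PROVISIONAL",
        ),
    ]
    # --- atlases
    t += [
        _T(
            "MRIO:0000647",
            "brain region atlas image data set",
            "An image data set consisting of values computed from multiple "
            "image data sets encoded to represent the spatial location of "
            "individual functional or structural regions of a canonical "
            "brain.",
            parent_iri="OBI:0003333",
        ),
        _T(
            DK_ATLAS,
            "Desikan-Killiany brain atlas image data set",
            "The Desikan-Killiany cortical parcellation with subcortical "
            "segmentation as used by FreeSurfer, covering 86 regions "
            "mapped to anatomy terms.",
            parent_iri="MRIO:0000647",
            synonyms=("Desikan-Killiany atlas",),
        ),
    ]
    return tuple(t)


def _axioms() -> tuple[TypeAxiom, ...]:
    C = Constraint
    flip90 = C("flip_deg", "equality", value=90.0, tolerance=0.5)
    t1_tr = C("tr_ms", "open_interval", low=0.0, high=800.0)
    t1_te = C("te_ms", "open_interval", low=0.0, high=30.0)
    t2_tr = C("tr_ms", "half_open", low=2000.0)
    t2_te = C("te_ms", "half_open", low=30.0)
    return (
        # Printed facet expressions: both bounds exclusive.
        TypeAxiom(T1W, (t1_tr, t1_te, flip90), provenance="PAPER"),
        TypeAxiom(T2W, (t2_tr, t2_te, flip90), provenance="PAPER"),
        # Named subtypes without printed facets: filled-in rules.
        TypeAxiom(
            FLAIR,
            (
                t2_tr,
                t2_te,
                flip90,
                C("ti_ms", "half_open", low=1500.0),
                C(
                    "scanning_sequence",
                    "categorical_membership",
                    allowed_values=frozenset({"IR"}),
                ),
            ),
            provenance="DEFAULT",
        ),
        TypeAxiom(
            PD,
            (t2_tr, C("te_ms", "open_interval", low=0.0, high=30.0), flip90),
            provenance="DEFAULT",
        ),
        # DWI: two axioms act as a disjunction (b value evidence OR
        # explicit diffusion gradients).
        TypeAxiom(
            DWI,
            (C("b_values", "half_open", low=0.0),),
            provenance="DEFAULT",
        ),
        TypeAxiom(
            DWI,
            (C("has_diffusion_gradients", "equality", value=True),),
            provenance="DEFAULT",
        ),
        TypeAxiom(
            FMRI,
            (
                C(
                    "scanning_sequence",
                    "categorical_membership",
                    allowed_values=frozenset({"EP"}),
                ),
                C("n_temporal_positions", "half_open", low=1.0),
            ),
            provenance="DEFAULT",
        ),
        TypeAxiom(
            SPGR,
            (
                C(
                    "scanning_sequence",
                    "categorical_membership",
                    allowed_values=frozenset({"GR"}),
                ),
                C("tr_ms", "open_interval", low=0.0, high=800.0),
                C("te_ms", "open_interval", low=0.0, high=30.0),
                C("flip_deg", "open_interval", low=0.0, high=45.0),
            ),
            provenance="DEFAULT",
        ),
    )


def _analyses() -> tuple[AnalysisSpec, ...]:
    A = AnalysisSpec
    return (
        A(
            SIENAX,
            "SIENAX analysis",
            input_dnf=((T1W, FLAIR), (T1W,)),
            outputs=(
                "whole brain volume measurement datum",
                "grey matter volume measurement datum",
                "white matter volume measurement datum",
                "CSF volume measurement datum",
            ),
            software_family="FSL",
            provenance="PAPER",
        ),
        A(
            "MRIOKIT:siena-analysis",
            "SIENA analysis",
            input_dnf=((T1W, T1W_FOLLOWUP),),
            outputs=("percent brain volume change measurement datum",),
            software_family="FSL",
            provenance="DEFAULT",
        ),
        A(
            "MRIOKIT:fast-analysis",
            "FAST analysis",
            input_dnf=((T1W,),),
            outputs=(
                "grey matter volume measurement datum",
                "white matter volume measurement datum",
                "CSF volume measurement datum",
            ),
            software_family="FSL",
            provenance="DEFAULT",
        ),
        A(
            "MRIOKIT:first-analysis",
            "FIRST analysis",
            input_dnf=((T1W,),),
            outputs=("subcortical structure volume measurement datum",),
            software_family="FSL",
            provenance="DEFAULT",
        ),
        A(
            "MRIOKIT:freesurfer-analysis",
            "FreeSurfer analysis",
            input_dnf=((T1W,),),
            outputs=(
                "tissue segmentation image data set",
                "regional volume measurement datum",
                "cortical thickness measurement datum",
            ),
            software_family="FreeSurfer",
            provenance="DEFAULT",
        ),
        A(
            "MRIOKIT:neurostream-analysis",
            "NeuroSTREAM analysis",
            input_dnf=((FLAIR,),),
            outputs=("lateral ventricle volume measurement datum",),
            software_family="NeuroSTREAM",
            provenance="DEFAULT",
        ),
        A(
            "MRIOKIT:deepgrai-analysis",
            "DeepGRAI analysis",
            input_dnf=((FLAIR,),),
            outputs=("thalamic volume measurement datum",),
            software_family="DeepGRAI",
            provenance="DEFAULT",
        ),
        A(
            "MRIOKIT:lpa-analysis",
            "LPA analysis",
            input_dnf=((T2W,),),
            outputs=("lesion probability map image data set",),
            software_family="SPM/LST",
            provenance="DEFAULT",
        ),
        A(
            "MRIOKIT:cpac-analysis",
            "C-PAC analysis",
            input_dnf=((FMRI,),),
            outputs=("functional connectome data set",),
            software_family="C-PAC",
            provenance="DEFAULT",
        ),
        A(
            "MRIOKIT:nemo-analysis",
            "NeMo analysis",
            input_dnf=((DWI,),),
            outputs=("network modification measurement datum",),
            software_family="NeMo",
            provenance="DEFAULT",
        ),
    )


def _bridge() -> tuple[TermBridge, ...]:
    B = TermBridge
    ms2s = 0.001
    return (
        # The echo-time entry is the worked bridging exemplar; the rest of
        # the table is completed from the DICOM data dictionary and BIDS
        # key names.
        B("MRIO:0000358", (0x0018, 0x0081), "EchoTime", "ms", "s", ms2s, "PAPER"),
        B("MRIO:0000357", (0x0018, 0x0080), "RepetitionTime", "ms", "s", ms2s, "DEFAULT"),
        B("MRIO:0000653", (0x0018, 0x0082), "InversionTime", "ms", "s", ms2s, "DEFAULT"),
        B("MRIO:0000630", (0x0018, 0x1314), "FlipAngle", "degree", "degree", 1.0, "DEFAULT"),
        B("MRIOKIT:scanning-sequence", (0x0018, 0x0020), "ScanningSequence", "code", "code", 1.0, "DEFAULT"),
        B("MRIO:0000362", (0x0018, 0x0050), "SliceThickness", "mm", "mm", 1.0, "DEFAULT"),
        B("MRIOKIT:spacing-between-slices", (0x0018, 0x0088), "SpacingBetweenSlices", "mm", "mm", 1.0, "DEFAULT"),
        B("MRIO:0000359", (0x0018, 0x0091), "EchoTrainLength", "count", "count", 1.0, "DEFAULT"),
        B("MRIO:0000687", (0x0020, 0x0105), "NumberOfTemporalPositions", "count", "count", 1.0, "DEFAULT"),
        B("MRIO:0000655", (0x0018, 0x9087), "DiffusionBValue", "s/mm^2", "s/mm^2", 1.0, "DEFAULT"),
        B("MRIO:0000690", (0x0018, 0x9075), "DiffusionDirectionality", "code", "code", 1.0, "DEFAULT"),
        B("MRIO:0000360", (0x0018, 0x1100), "FieldOfView", "mm", "mm", 1.0, "DEFAULT"),
        B("MRIO:0000365", (0x0018, 0x1312), "InPlanePhaseEncodingDirectionDICOM", "code", "code", 1.0, "DEFAULT"),
        B("MRIO:0000361", (0x0018, 0x0094), "PercentPhaseFieldOfView", "percent", "percent", 1.0, "DEFAULT"),
        B("MRIO:0000364", (0x0018, 0x1310), "AcquisitionMatrix", "count", "count", 1.0, "DEFAULT"),
    )


# 34 Desikan-Killiany cortical parcels per hemisphere (FreeSurfer naming).
_DK_CORTICAL = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

# Subcortical / non-cortical segmentation labels (9 per hemisphere), with
# anatomy cross-references where a specific term is curated.  Regions
# without a curated specific identifier carry the generic brain structure
# placeholder UBERON:0000955, flagged for later curation.
_PLACEHOLDER = "UBERON:0000955"
_DK_SUBCORTICAL = (
    ("Thalamus", "UBERON:0001897"),
    ("Caudate", "UBERON:0001873"),
    ("Putamen", "UBERON:0001874"),
    ("Pallidum", "UBERON:0001875"),
    ("Hippocampus", "UBERON:0002421"),
    ("Amygdala", "UBERON:0001876"),
    ("Accumbens-area", "UBERON:0001882"),
    ("Cerebellum-Cortex", "UBERON:0002129"),
    ("VentralDC", _PLACEHOLDER),
)


def _atlas() -> AtlasMap:
    regions = []
    for hemi in ("lh", "rh"):
        for name in _DK_CORTICAL:
            regions.append(AtlasRegion(f"{hemi}-{name}", _PLACEHOLDER))
    for side in ("Left", "Right"):
        for name, xref in _DK_SUBCORTICAL:
            regions.append(AtlasRegion(f"{side}-{name}", xref))
    assert len(regions) == 86
    return AtlasMap(DK_ATLAS, tuple(regions))


def bundled_kb() -> KnowledgeBase:
    return KnowledgeBase(
        terms=_terms(),
        axioms=_axioms(),
        analyses=_analyses(),
        bridge=_bridge(),
        atlases=(_atlas(),),
    )
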