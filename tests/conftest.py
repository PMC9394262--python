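import pytest

from mitocomp.syndata import (
    IntronPlant,
    OrfPlant,
    RepeatPlant,
    SynthSpec,
    generate_cohort,
    study_cohort_spec,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Four moderately diverged genomes with introns, ORFs, repeats and one
    minus-strand gene, shared by read/write and geometry tests."""
    spec = SynthSpec(
        n_genomes=4,
        divergence=0.05,
        genome_length_target=32_000,
        seed=11,
        intron_plants=(
            IntronPlant("G01", "cox1", 100, 600),
            IntronPlant("G01", "cox1", 1305, 700, with_orf=True),
            IntronPlant("G02", "cox1", 1305, 700, with_orf=True),
            IntronPlant("G02", "nad5", 426, 500),
            IntronPlant("G03", "nad5", 426, 500),
        ),
        repeat_plants=(
            RepeatPlant("G01", 100, 2, label="dup"),
            RepeatPlant("G02", 45, 3, tandem=True, label="tand"),
        ),
        orf_plants=(OrfPlant("rnapol", ("G01", "G02", "G03"), 109, "RNA polymerase"),),
        minus_strand_genes=("cox2",),
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def study_cohort():
    """The 13-genome study-condition cohort."""
    return generate_cohort(study_cohort_spec(seed=3))


@pytest.fixture(scope="session")
def study_records(study_cohort):
    return study_cohort[0]


@pytest.fixture(scope="session")
def study_truth(study_cohort):
    return study_cohort[1]
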