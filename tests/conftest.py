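import pytest

from recombkin.design import LIBRARY2, LibraryDesign


@pytest.fixture(scope="session")
def library2() -> LibraryDesign:
    return LIBRARY2


@pytest.fixture(scope="session")
def toy_design() -> LibraryDesign:
    """Two variable positions, one conserved position; exhaustively checkable."""
    return LibraryDesign(
        name="toy2",
        variable_positions=(2, 3),
        wt_bases=("C", "G"),
        conserved_positions={4: "T"},
        reference_halfsite="ACGT",
    )


@pytest.fixture(scope="session")
def toy3_design() -> LibraryDesign:
    """Three variable positions (64 variants) for small pipeline round trips."""
    return LibraryDesign(
        name="toy3",
        variable_positions=(1, 3, 5),
        wt_bases=("A", "G", "T"),
        conserved_positions={2: "C"},
        reference_halfsite="ACGAT",
    )


@pytest.fixture(scope="session")
def benchmark_result():
    """One full synthetic library-2 selection-and-fit round trip (seeded).

    Session-scoped: the simulation (5e5 reads over 262,144 variants) is run
    once and shared by the tests that interrogate different aspects of it.
    """
    from recombkin.pipeline import library2_selection_benchmark

    return library2_selection_benchmark(seed=1)
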