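"""Regenerate the bundled synthetic stand-in matrix (deterministic).

The real 25 x 30 morphological matrix lives on MorphoBank (project P2506,
matrix 24392) and is not redistributable here, so the package ships a
synthetic stand-in of identical shape: 24 extant genera plus the fossil
taxon, 30 characters partitioned 25 floral / 5 foliar.  Characters are
simulated under Mk(3) on the bundled Hauenschild-style backbone with the
fossil attached on the Paliureae stem (its most-parsimonious position in
the original analysis), light missingness everywhere, and heavy
missingness plus a little polymorphism on the fossil row, emulating a
partially preserved flower.

Run from the repository root:  python scripts/build_fixtures.py
"""

from pathlib import Path

from fossilplace.matrix_io import write_nexus
from fossilplace.scaffold import bundled_scaffold
from fossilplace.simulate import SimulationConfig, degrade_matrix, simulate_characters

OUT = Path(__file__).resolve().parent.parent / "src" / "fossilplace" / "data"
SEED = 20170601
BRANCH_LENGTH = 0.25  # expected changes per character per branch
FOSSIL = "Notiantha"


def main() -> None:
    scaffold = bundled_scaffold("hauenschild2016")
    paliureae_stem = scaffold.clades["Paliureae"]
    tree = scaffold.topology.attach_leaf(paliureae_stem, FOSSIL)
    for node in tree.postorder():
        if node.parent is not None:
            node.length = BRANCH_LENGTH
    config = SimulationConfig(tree=tree, n_characters=30, n_states=3, seed=SEED)
    matrix, _ = simulate_characters(config)
    # light incompleteness across the extant genera (~7% of cells)
    matrix = degrade_matrix(
        matrix,
        frozenset(t for t in matrix.taxa if t != FOSSIL),
        missing_fraction=0.07,
        polymorphic_fraction=0.0,
        seed=SEED + 1,
        n_states=3,
    )
    # a partially preserved fossil: ~30% missing, a couple of widened cells
    matrix = degrade_matrix(
        matrix,
        frozenset([FOSSIL]),
        missing_fraction=0.30,
        polymorphic_fraction=0.07,
        seed=SEED + 2,
        n_states=3,
    )
    write_nexus(matrix, OUT / "standin_matrix_synthetic.nex")
    text = (OUT / "standin_matrix_synthetic.nex").read_text()
    header = (
        "[ SYNTHETIC stand-in for the MorphoBank P2506 matrix (24392): same\n"
        "  shape (25 taxa x 30 characters, 25 floral + 5 foliar) but simulated\n"
        "  Mk(3) characters, NOT the real observations.  Regenerate with\n"
        "  scripts/build_fixtures.py ]\n"
    )
    (OUT / "standin_matrix_synthetic.nex").write_text(
        text.replace("#NEXUS\n", "#NEXUS\n" + header, 1)
    )
    print(f"wrote {OUT / 'standin_matrix_synthetic.nex'}")


if __name__ == "__main__":
    main()
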