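"""A synthetic 33-species time tree for the quantity-discrimination analysis.

The comparative dataset this package targets spans 33 bird and mammal
species (15 of them primates).  The original species list and supertree are
not redistributable, so this module assembles a *synthetic* stand-in with
the same taxonomic shape: 10 birds, 8 nonprimate mammals and 15 primates,
with node ages rounded from the TimeTree literature.  Two recent splits the
supertree lacks are added by grafting, exactly as the analysis pipeline
would: the North/South Island robin divergence at 3 Myr and the dog/wolf
divergence at 15 000 years (0.015 Myr).

Only those two grafted ages are treated as exact anywhere in the package;
all other ages are plausible round numbers and carry no analysis weight
beyond giving the correlation matrix a realistic block structure.
"""

from __future__ import annotations

from .phylogeny import PhyloTree, graft_split, load_tree

ROBIN_SPLIT_MYR = 3.0
DOG_WOLF_SPLIT_MYR = 0.015

# Nested (age_Myr, [children]) structure; leaves are plain labels (age 0).
_BIRDS = (
    105.0,
    [
        "chicken",
        (
            90.0,
            [
                "pigeon",
                (
                    64.0,
                    [
                        (60.0, ["kea", (50.0, ["grey_parrot", "budgerigar"])]),
                        (
                            45.0,
                            [
                                "north_island_robin",
                                (
                                    22.0,
                                    [
                                        "blue_jay",
                                        (17.0, ["carrion_crow", "clarks_nutcracker"]),
                                    ],
                                ),
                            ],
                        ),
                    ],
                ),
            ],
        ),
    ],
)

_PRIMATES = (
    74.0,
    [
        (20.0, ["ring_tailed_lemur", "mongoose_lemur"]),
        (
            43.0,
            [
                (
                    24.0,
                    [
                        "spider_monkey",
                        (
                            20.5,
                            [
                                "common_marmoset",
                                (16.0, ["tufted_capuchin", "squirrel_monkey"]),
                            ],
                        ),
                    ],
                ),
                (
                    29.0,
                    [
                        (
                            13.0,
                            [
                                "vervet_monkey",
                                (
                                    10.0,
                                    [
                                        (3.5, ["rhesus_macaque", "long_tailed_macaque"]),
                                        (2.0, ["olive_baboon", "hamadryas_baboon"]),
                                    ],
                                ),
                            ],
                        ),
                        (
                            16.0,
                            [
                                "orangutan",
                                (9.0, ["gorilla", (2.1, ["chimpanzee", "bonobo"])]),
                            ],
                        ),
                    ],
                ),
            ],
        ),
    ],
)

_MAMMALS = (
    99.0,
    [
        "african_elephant",
        (
            94.0,
            [
                _PRIMATES,
                (
                    78.0,
                    [
                        "bottlenose_dolphin",
                        (
                            76.0,
                            [
                                "horse",
                                (
                                    54.0,
                                    [
                                        "domestic_cat",
                                        (
                                            48.0,
                                            [
                                                "south_american_sea_lion",
                                                (1.0, ["coyote", "wolf"]),
                                            ],
                                        ),
                                    ],
                                ),
                            ],
                        ),
                    ],
                ),
            ],
        ),
    ],
)

_ROOT = (320.0, [_BIRDS, _MAMMALS])


def _newick(node, parent_age: float | None = None) -> str:
    """Render an (age, children) nest as Newick with lengths = age gaps."""
    if isinstance(node, str):
        return f"{node}:{parent_age:g}"
    age, children = node
    if parent_age is not None and age >= parent_age:
        raise ValueError(f"node age {age} not younger than parent {parent_age}")
    inner = ",".join(_newick(c, age) for c in children)
    if parent_age is None:
        return f"({inner});"
    return f"({inner}):{parent_age - age:g}"


def base_newick() -> str:
    """Newick of the 31-tip supertree before the two grafts."""
    return _newick(_ROOT)


def study_species_tree() -> PhyloTree:
    """The full 33-tip synthetic analysis tree.

    Loads the 31-tip base supertree, then grafts the South Island robin onto
    the North Island robin at 3 Myr and the dog onto the wolf at 0.015 Myr.
    """
    tree = load_tree(base_newick())
    tree = graft_split(
        tree, "north_island_robin", "south_island_robin", ROBIN_SPLIT_MYR
    )
    tree = graft_split(tree, "wolf", "dog", DOG_WOLF_SPLIT_MYR)
    return tree


PRIMATES = (
    "ring_tailed_lemur",
    "mongoose_lemur",
    "spider_monkey",
    "common_marmoset",
    "tufted_capuchin",
    "squirrel_monkey",
    "vervet_monkey",
    "rhesus_macaque",
    "long_tailed_macaque",
    "olive_baboon",
    "hamadryas_baboon",
    "orangutan",
    "gorilla",
    "chimpanzee",
    "bonobo",
)

BIRDS = (
    "chicken",
    "pigeon",
    "kea",
    "grey_parrot",
    "budgerigar",
    "north_island_robin",
    "south_island_robin",
    "blue_jay",
    "carrion_crow",
    "clarks_nutcracker",
)
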