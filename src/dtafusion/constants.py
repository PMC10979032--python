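"""Frozen feature dictionaries and size caps.

Changing any value here changes every downstream embedding index, so treat
this file as versioned: additions go at the end, existing codes never move.
Unknown raw values map to the reserved code ``len(dictionary)``.
"""

DICTIONARY_VERSION = 1

# heavy-atom count cap for the per-atom molecule-size slot and position index
MAX_ATOM_COUNT = 128
MAX_DEGREE = 16
MAX_NUM_H = 8
MAX_RADICALS = 4

# shortest-path-distance bucket cap; one extra bucket marks unreachable pairs
MAX_SPD_BUCKET = 20

CHIRALITY = ["none", "R", "S", "axial", "planar", "helical"]

ELEMENTS = [
    "C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B",
    "Si", "Se", "Na", "K", "Li", "Ca", "Mg", "Zn", "Fe", "H",
]

HYBRIDIZATIONS = ["S", "SP", "SP2", "SP3", "SP3D", "SP3D2", "UNSPECIFIED"]

FORMAL_CHARGES = [-2, -1, 0, 1, 2]

BOND_TYPES = ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC"]

BOND_STEREO = ["STEREONONE", "STEREOANY", "STEREOZ", "STEREOE",
               "STEREOCIS", "STEREOTRANS"]

# vocabulary sizes including the reserved unknown code
N_CHIRALITY = len(CHIRALITY) + 1
N_ELEMENTS = len(ELEMENTS) + 1
N_HYBRID = len(HYBRIDIZATIONS) + 1
N_CHARGE = len(FORMAL_CHARGES) + 1
N_BOND_TYPES = len(BOND_TYPES) + 1
N_BOND_STEREO = len(BOND_STEREO) + 1

# one-hot width of a bond feature vector (type | stereo | conjugated flag)
BOND_ONEHOT_WIDTH = N_BOND_TYPES + N_BOND_STEREO + 1

SS8_ALPHABET = "HGIEBTSC"

# Wilke (Tien et al. 2013) maximum accessible surface areas, A^2, for
# normalising absolute ASA inputs to relative accessibility in [0, 1].
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def code(dictionary, value):
    """Index of ``value`` in ``dictionary``; the reserved code if absent."""
    try:
        return dictionary.index(value)
    except ValueError:
        return len(dictionary)
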