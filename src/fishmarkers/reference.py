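"""Bundled reference marker panels for six fish species.

Curated species-specific MALDI-TOF m/z marker lists (raw and cooked meat of
carp, mackerel, pike, pollock, salmon and trout), raw-vs-cooked differential
marker lists, and the carp characteristic-peptide sequences identified by
LC-ESI-Q-TOF with their printed fragment masses.  These small panels drive
the examples and the cross-platform validation: they are *inputs* to the
matching and pairing operations, not outputs of this package.

m/z values are singly protonated ion masses reported to one decimal; peptide
masses are neutral monoisotopic fragment masses to two decimals.
"""

from __future__ import annotations

__all__ = [
    "SPECIES",
    "SPECIES_MARKERS",
    "STATE_MARKERS",
    "CARP_CHARACTERISTIC_PEPTIDES",
]

SPECIES = ("carp", "mackerel", "pike", "pollock", "salmon", "trout")

# Species-exclusive MALDI markers, mined independently for raw and for cooked
# meat: {state: {species: [m/z, ...]}}
SPECIES_MARKERS: dict[str, dict[str, list[float]]] = {
    "raw": {
        "carp": [1093.7, 1263.6, 1309.7, 1432.7, 1770.8, 2101.1, 2263.3],
        "mackerel": [934.6, 1269.7, 1380.8, 1397.9, 1411.8, 1463.7, 1777.0,
                     1836.0, 1932.2, 2023.2, 2095.2, 2291.4, 2638.6, 4048.3],
        "pike": [1226.6, 2587.5, 4165.5],
        "pollock": [1142.8, 1325.8, 1564.3, 1632.2, 1800.5, 1866.6, 2221.6,
                    2553.6, 2635.2],
        "salmon": [1868.2, 1980.4, 2059.1],
        "trout": [1109.9, 3175.6],
    },
    "cooked": {
        "carp": [1093.7, 1137.5, 1180.5, 1633.6, 1770.8, 2101.1, 2185.0,
                 2317.1, 2484.2, 2732.1],
        "mackerel": [934.6, 1050.6, 1115.7, 1239.8, 1269.8, 1296.8, 1308.7,
                     1380.9, 1397.9, 1411.8, 1506.8, 1725.2, 1777.1, 1838.2,
                     1932.1, 2291.5, 2392.4],
        "pike": [1355.9, 2587.5, 2723.7, 3458.3, 4165.5],
        "pollock": [1142.9, 1325.9, 1339.0, 1384.0, 1409.1, 1561.2, 1632.2,
                    1774.6, 1780.7, 1800.5, 1866.7, 1890.6, 1895.7, 2221.7,
                    3183.5],
        "salmon": [2059.1, 3291.4],
        "trout": [1344.6, 1565.7, 3175.6],
    },
}

# Raw-vs-cooked differential markers of the same species:
# {species: {state: [m/z, ...]}}
STATE_MARKERS: dict[str, dict[str, list[float]]] = {
    "carp": {
        "raw": [1050.6, 1127.7, 1309.8, 1383.7, 1500.8, 1561.9, 1569.9,
                1877.3, 2480.2],
        "cooked": [1661.6, 2184.9, 2446.1, 2732.1],
    },
    "mackerel": {
        "raw": [914.5, 1028.6, 1127.7, 1643.9, 1650.9, 2023.2, 2115.1],
        "cooked": [909.6, 1239.8, 2216.4],
    },
    "pike": {
        "raw": [1127.7, 1226.8, 1358.9, 1402.8],
        "cooked": [1279.9, 1908.4],
    },
    "pollock": {
        "raw": [1254.9, 1740.0],
        "cooked": [1470.0],
    },
    "salmon": {
        "raw": [1002.5, 1050.6, 1067.6, 1127.7, 1269.7, 1296.8, 1339.7,
                1397.8, 1411.8, 1506.9, 1682.0, 1777.0, 1932.0, 4048.3],
        "cooked": [1135.5, 1237.6, 1476.7, 1488.7, 1754.8, 1854.7, 2003.0,
                   2384.2, 2512.4],
    },
    "trout": {
        "raw": [1240.8, 1358.8, 1536.1, 1560.0, 1705.0],
        "cooked": [1400.6, 2118.9, 2406.1, 2438.0, 3414.6, 3471.7],
    },
}

# Carp characteristic peptides whose masses coincide with a MALDI marker:
# {state: [(flanked sequence, printed fragment mass Da, protein name), ...]}
CARP_CHARACTERISTIC_PEPTIDES: dict[str, list[tuple[str, float, str]]] = {
    "raw": [
        ("K.GFTLPTTNSR.G", 1092.56, "Creatine kinase, muscle b"),
        ("K.VAFNQVADIMR.A", 1262.64, "LanC synthetase component C-like"),
        ("R.IDFDAFLPMLK.S", 1308.68, "Myosin light chain 3, skeletal muscle isoform"),
    ],
    "cooked": [
        ("K.GFTLPTTNSR.G", 1092.56, "Creatine kinase, muscle b"),
        ("K.NALAHAVQSAR.H", 1136.61, "Myosin heavy chain, fast skeletal muscle"),
        ("R.LQTENGEFSR.Q", 1179.55, "Myosin heavy chain, fast skeletal muscle"),
        ("K.GILGYTEDQVVSTDFNGDVR.S", 2184.03, "Glyceraldehyde-3-phosphate dehydrogenase"),
    ],
}
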