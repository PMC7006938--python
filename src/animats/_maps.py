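"""Bundled ASCII maps (see world.py for the legend and provenance)."""

ORIGINAL = """\
################################
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............G...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
################################
"""

NOISY_CORNERS = """\
################################
###..........#####...........###
###..........#####...........###
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............G...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
###..........#####...........###
###..........#####...........###
################################
"""

SMALL_GATE = """\
################################
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S#####S.S.S.S.S.S..#
#............#.#.#.............#
#..............G...............#
#............#.#.#.............#
#............#####.............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
################################
"""

FOUR_ROOMS = """\
################################
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
#..............#...............#
#..............G...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#######G###############G########
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..G..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
################################
"""

FOUR_MESSY_ROOMS = """\
################################
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#....##........#.........#.....#
#..............#.........#.....#
#..............G...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#.........#....#....##.........#
#.........#....#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#######g###############g########
#..............#...............#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#....#.........#.........##....#
#....#.........#...............#
#..............#...............#
#.S.S.S.S.S.S..G..S.S.S.S.S.S..#
#..............#...............#
#.........##...#...............#
#.........##...#....#..........#
#..............#...............#
#.S.S.S.S.S.S..#..S.S.S.S.S.S..#
#..............#...............#
#..............#...............#
################################
"""
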