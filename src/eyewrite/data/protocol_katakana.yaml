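# Default eye-writing input protocol for Japanese Katakana.
#
# Three levels: 11 basic motion units (9 directional gaze motions + blink +
# sil), 12 reusable stroke classes expressed as motion sequences, and a
# 70-character lexicon (48 basic Katakana + 22 derived characters carrying
# dakuten/handakuten marks) expressed as stroke sequences.
#
# This table is editable data, not code.  Several characters intentionally
# share an identical motion expansion (homographs under the protocol); the
# character N-gram is responsible for disambiguating them during decoding.

units:
  - up
  - down
  - left
  - right
  - upper_left
  - upper_right
  - lower_left
  - lower_right
  - center_return
  - blink
  - sil

sil_policy: both   # sil inserted between strokes and between characters

strokes:
  1:  [down]                             # vertical bar
  2:  [right]                            # horizontal bar
  3:  [upper_right]                      # short rising stroke
  4:  [lower_left]                       # left-falling sweep
  5:  [lower_right]                      # short right-falling stroke
  6:  [right, down]                      # top-right corner
  7:  [right, lower_left]                # horizontal into left sweep
  8:  [down, lower_left]                 # vertical curving left
  9:  [down, right]                      # L-shaped bottom hook
  10: [down, upper_right]                # vertical with rising tail
  11: [left, up, right, down, left]      # closed box
  12: [blink]                            # dot / diacritic tick

# Mark strokes appended to a base character to derive voiced forms.
marks:
  dakuten: [5, 5]
  handakuten: [11]

characters:
  ア: {strokes: [2, 8],         romaji: a}
  イ: {strokes: [4, 1],         romaji: i}
  ウ: {strokes: [12, 6, 4],     romaji: u}
  エ: {strokes: [2, 1, 2],      romaji: e}
  オ: {strokes: [2, 1, 4],      romaji: o}
  カ: {strokes: [8, 6],         romaji: ka}
  キ: {strokes: [3, 2, 1],      romaji: ki}
  ク: {strokes: [4, 6],         romaji: ku}
  ケ: {strokes: [4, 2, 1],      romaji: ke}
  コ: {strokes: [6, 2],         romaji: ko}
  サ: {strokes: [2, 1, 5],      romaji: sa}
  シ: {strokes: [12, 12, 3],    romaji: shi}
  ス: {strokes: [6, 5],         romaji: su}
  セ: {strokes: [2, 9],         romaji: se}
  ソ: {strokes: [12, 4],        romaji: so}
  タ: {strokes: [4, 6, 5],      romaji: ta}
  チ: {strokes: [3, 2, 1],      romaji: chi}
  ツ: {strokes: [12, 12, 4],    romaji: tsu}
  テ: {strokes: [2, 2, 1],      romaji: te}
  ト: {strokes: [1, 5],         romaji: to}
  ナ: {strokes: [2, 4],         romaji: na}
  ニ: {strokes: [2, 2],         romaji: ni}
  ヌ: {strokes: [6, 5, 4],      romaji: nu}
  ネ: {strokes: [12, 6, 1],     romaji: ne}
  ノ: {strokes: [4],            romaji: no}
  ハ: {strokes: [4, 5],         romaji: ha}
  ヒ: {strokes: [3, 9],         romaji: hi}
  フ: {strokes: [6],            romaji: fu}
  ヘ: {strokes: [3, 5],         romaji: he}
  ホ: {strokes: [2, 1, 12],     romaji: ho}
  マ: {strokes: [6, 12],        romaji: ma}
  ミ: {strokes: [3, 3, 3],      romaji: mi}
  ム: {strokes: [9, 12],        romaji: mu}
  メ: {strokes: [4, 3],         romaji: me}
  モ: {strokes: [2, 2, 9],      romaji: mo}
  ヤ: {strokes: [3, 6, 1],      romaji: ya}
  ユ: {strokes: [6, 2],         romaji: yu}
  ヨ: {strokes: [6, 2, 2],      romaji: yo}
  ラ: {strokes: [2, 6],         romaji: ra}
  リ: {strokes: [1, 8],         romaji: ri}
  ル: {strokes: [4, 10],        romaji: ru}
  レ: {strokes: [10],           romaji: re}
  ロ: {strokes: [11],           romaji: ro}
  ワ: {strokes: [6, 8],         romaji: wa}
  ヰ: {strokes: [3, 1, 2],      romaji: wi}
  ヱ: {strokes: [6, 1, 2],      romaji: we}
  ヲ: {strokes: [2, 6, 3],      romaji: wo}
  ン: {strokes: [12, 3],        romaji: n}
  ガ: {base: カ, mark: dakuten,    romaji: ga}
  ギ: {base: キ, mark: dakuten,    romaji: gi}
  グ: {base: ク, mark: dakuten,    romaji: gu}
  ゲ: {base: ケ, mark: dakuten,    romaji: ge}
  ゴ: {base: コ, mark: dakuten,    romaji: go}
  ザ: {base: サ, mark: dakuten,    romaji: za}
  ジ: {base: シ, mark: dakuten,    romaji: ji}
  ズ: {base: ス, mark: dakuten,    romaji: zu}
  ゼ: {base: セ, mark: dakuten,    romaji: ze}
  ゾ: {base: ソ, mark: dakuten,    romaji: zo}
  ダ: {base: タ, mark: dakuten,    romaji: da}
  ヂ: {base: チ, mark: dakuten,    romaji: dji}
  ヅ: {base: ツ, mark: dakuten,    romaji: dzu}
  デ: {base: テ, mark: dakuten,    romaji: de}
  ド: {base: ト, mark: dakuten,    romaji: do}
  バ: {base: ハ, mark: dakuten,    romaji: ba}
  ビ: {base: ヒ, mark: dakuten,    romaji: bi}
  ブ: {base: フ, mark: dakuten,    romaji: bu}
  ベ: {base: ヘ, mark: dakuten,    romaji: be}
  ボ: {base: ホ, mark: dakuten,    romaji: bo}
  パ: {base: ハ, mark: handakuten, romaji: pa}
  ピ: {base: ヒ, mark: handakuten, romaji: pi}
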