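>IHMU synthetic stand-in reference HNH endonuclease
LNSIFKGWAHCRKLYPTPLGQNTRGTPEGSDLLIPRNVRTVETAKNGTGGNLAQEEAQLIAIRGDRLIAP
EIGDHNKDLLLDMIYISPQFTLGSGNLMIVLFALRKLRFPLFDINDHLKINIPMSINHCASQLDAIQPGI
TKQADGIHWAVGTPWTQFYDKGAAGLLWILVEDAMYNKGDDNTDSIIKAI
>PACI synthetic stand-in reference HNH endonuclease
LIPAAGLINRHSHLADPALEAEAVEELGVAGEIQLSRRDKPHICLEIRDLYLNFRAVINEIGDHNKDLLL
DMIYISPIFTNGSGNLMIVLFALRKLREPLFDIRDNLQIEGQATSDRREEEIINTEHQDPRIWHVELTFE
GIIGNLLFLPPPDALRRSPE
>GVE2 synthetic stand-in reference HNH endonuclease
SLEGRHGVDRELACGEAADQRDVMVGKPEVGKTAGHHEALHDTLVVKLQVVLINTGELEVAAVSLLESDT
VGKVSPETGDHNYDLLLPHIYISPQFTLGSGNIMIVLFALRRAKWPLFDIQDHLKIFLMGVDENFVIAAA
AIDGDTGGRNTEYYGLAYARDQIDLNHYVAELEGKNLIAMLGTELGAYFMFEAQTNTDLAESEYGPQGAN
ASLKVFHPIL
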