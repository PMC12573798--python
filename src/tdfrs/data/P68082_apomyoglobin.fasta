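>P68082_mature horse heart apomyoglobin, mature chain (initiator Met removed), 153 aa
GLSDGEWQQVLNVWGKVEADIAGHGQEVLIRLFTGHPETLEKFDKFKHLKTEAEMKASED
LKKHGTVVLTALGGILKKKGHHEAELKPLAQSHATKHKIPIKYLEFISDAIIHVLHSKHP
GDFGADAQGAMTKALELFRNDIAAKYKELGFQG
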