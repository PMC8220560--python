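>DRB1*04:01
MAGEVHFDYYYSYDYLQKATVGTQEAHNLTVDLTR
>DRB1*04:02
MAGEVHFDYYYSYDYIDEATVVTQEAHNLTVDLTR
>DRB1*04:03
MAGEVHFDYYYSYDYLQRESVVAQESHNLTVDLTR
>DRB1*04:04
MAGWVHFDYYYSYDYLQRATVVTQEAHNLTVDLTR
>DRB1*04:05
MAGEVHFDYYYSYSYIDRATVGTQEAHNLTVDLTR
>DRB1*04:06
MAGEVHFDYYSSYDYLQKATVVTQEAHNLTVDLTR
>DRB1*04:07
MAGEVHFDYYYSYDYLQRESVGAQESHNLTVDLTR
>DRB1*04:08
MAGEVHFDYYYSYDYLQRATVGTQEAHNLTVDLTR
>DRB1*04:10
MAGWVHFDYYYSYDYLQRATVVTQEAHNLTVALTR
>DRB1*04:13
MAGEVHFDYYYSYDYLQRATVGTEEAHNLTVDLTR
>DRB1*01:01
MAGWLFLECHYFWDHLQRATVGTQEAQNLTVDLTR
>DRB1*03:01
MAGKSSYNHYYSFDSLQKRNVVRQEAHNLTVDLTR
>DRB1*03:02
MAGKSSYNHYYSFDSLQKRNVGRQKAHNLTVDLTR
>DRB1*07:01
MAGQGYWEYNYAYDLFRRQTVGTQEAHSLTVDLTR
>DRB1*08:01
MAGDSGFHGYYTLDYLQRLTVGTQEAHNMTADLTR
>DRB1*15:01
MTGWPRIQVFYSADYLQAATVGTQEAHNLSADLTR
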