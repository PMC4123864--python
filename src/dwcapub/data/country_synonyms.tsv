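# variant<TAB>canonical code. Matching is case/punctuation/whitespace-insensitive.
USA	US
United State	US
U.S.A.	US
United States of America	US
US.	US
United States	US
Estados Unidos	US
UK	GB
Great Britain	GB
United Kingdom	GB
Deutschland	DE
Germany	DE
Brasil	BR
Brazil	BR
Mexico	MX
México	MX
Canada	CA
Australia	AU
France	FR
España	ES
Spain	ES
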