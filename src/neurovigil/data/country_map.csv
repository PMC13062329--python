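raw,normalized
US,United States of America
USA,United States of America
UNITED STATES,United States of America
UNITED STATES OF AMERICA,United States of America
JP,Japan
JAPAN,Japan
FR,France
FRANCE,France
DE,Germany
GERMANY,Germany
CN,China
CHINA,China
CA,Canada
CANADA,Canada
GB,United Kingdom
UK,United Kingdom
UNITED KINGDOM,United Kingdom
IT,Italy
ITALY,Italy
AU,Australia
AUSTRALIA,Australia
ES,Spain
SPAIN,Spain
BR,Brazil
BRAZIL,Brazil
KR,Republic of Korea
KOREA,Republic of Korea
REPUBLIC OF KOREA,Republic of Korea
NL,Netherlands
NETHERLANDS,Netherlands
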